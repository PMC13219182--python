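import numpy as np
import pytest

from combokg.kg import EntityVocab, KnowledgeGraph, RelationVocab, augment_relations


def toy_kg(augment: bool = True) -> KnowledgeGraph:
    """Two drugs each targeting two genes; one gene linked to one disease."""
    v = EntityVocab()
    for name, t in [
        ("d1", "drug"), ("d2", "drug"),
        ("g1", "gene"), ("g2", "gene"), ("g3", "gene"), ("g4", "gene"),
        ("s1", "disease"),
    ]:
        v.add(name, t)
    r = RelationVocab()
    rt = r.add("targets")
    ra = r.add("associated_with")
    trips = {
        (v.index["d1"], rt, v.index["g1"]),
        (v.index["d1"], rt, v.index["g2"]),
        (v.index["d2"], rt, v.index["g3"]),
        (v.index["d2"], rt, v.index["g4"]),
        (v.index["g1"], ra, v.index["s1"]),
    }
    kg = KnowledgeGraph(vocab=v, relations=r, triples=trips)
    if augment:
        from combokg.subgraph import prepare_kg

        kg = prepare_kg(kg)
    return kg


@pytest.fixture
def kg_toy():
    return toy_kg()


@pytest.fixture
def kg_toy_raw():
    return toy_kg(augment=False)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def write_tsvs(tmp_path, triples, types):
    tp = tmp_path / "triples.tsv"
    yp = tmp_path / "types.tsv"
    tp.write_text("".join(f"{h}\t{r}\t{t}\n" for h, r, t in triples))
    yp.write_text("".join(f"{e}\t{t}\n" for e, t in types))
    return str(tp), str(yp)
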