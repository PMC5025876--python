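import pytest

import clonmix as cm
from clonmix.annotation import AnnotatedSequence, mutation_from_parts
from clonmix.clonality import Clone


@pytest.fixture(scope="session")
def ref():
    return cm.default_germline()


@pytest.fixture(scope="session")
def make_annotated(ref):
    """Factory for annotation objects carrying a prescribed mutation set."""

    def factory(seq_id, muts, mouse="m1", compartment="PP", subset="MEMORY",
                cdr3_nt="GCTAGATAT", n_indels=0):
        rec = cm.SequenceRecord(seq_id, ref.nt_seq, mouse, compartment, subset, "IgA")
        ann = AnnotatedSequence(record=rec)
        fixed = [
            (p, b if b != ref.base(p) else ("C" if ref.base(p) != "C" else "G"))
            for p, b in sorted(muts)
        ]
        ann.mutations = [
            mutation_from_parts(p, ref.base(p), b, ref) for p, b in fixed
        ]
        ann.n_mutations = len(ann.mutations)
        ann.n_indels = n_indels
        ann.cdr3_nt = cdr3_nt
        ann.cdr3_aa = "AYY"[: len(cdr3_nt) // 3] if cdr3_nt else None
        return ann

    return factory


@pytest.fixture(scope="session")
def make_clone():
    def factory(clone_id, members, mouse="m1", pairs=None):
        pairs = pairs or [("PP", "MEMORY")] * len(members)
        return Clone(
            clone_id=clone_id,
            mouse_id=mouse,
            member_ids=list(members),
            cdr3_len=3,
            representative_junction="GCTAGATAT",
            compartments=pairs,
        )

    return factory


@pytest.fixture(scope="session")
def long_run(ref):
    """One paper-scale resting-regime repertoire, annotated and grouped."""
    cfg = cm.paper_scale_preset("long", seed=101)
    records, truth = cm.simulate_repertoire(cfg, ref)
    dataset = cm.annotate(records, ref)
    clones, unassigned = cm.group_clones(dataset)
    cm.flag_clonal_cdr3_changes(dataset, clones)
    return {
        "config": cfg,
        "records": records,
        "truth": truth,
        "dataset": dataset,
        "clones": clones,
        "unassigned": unassigned,
    }
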