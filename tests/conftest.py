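import pytest

from srsanon import (
    AttributeSchema,
    QIDGroup,
    SRSRecord,
    TaxonomyTree,
    binary_gender_tree,
    make_qid,
)


@pytest.fixture(scope="session")
def age_taxonomy() -> TaxonomyTree:
    """Toy age taxonomy: ANY -> {Nonadult, Adult},
    Nonadult -> {Newborn, Preschool, Adolescent}.  Height 2."""
    return TaxonomyTree(root="ANY", parent={
        "Nonadult": "ANY", "Adult": "ANY",
        "Newborn": "Nonadult", "Preschool": "Nonadult", "Adolescent": "Nonadult",
    })


@pytest.fixture(scope="session")
def cat_schema(age_taxonomy):
    """Two categorical attributes: Gender (height 1) and Age (height 2)."""
    return (
        AttributeSchema(name="Gender", kind="categorical", taxonomy=binary_gender_tree()),
        AttributeSchema(name="Age", kind="categorical", taxonomy=age_taxonomy),
    )


@pytest.fixture(scope="session")
def mixed_schema():
    """Gender (categorical) + Age in years over a global range of [30, 40]."""
    return (
        AttributeSchema(name="Sex", kind="categorical", taxonomy=binary_gender_tree()),
        AttributeSchema(name="Age", kind="numeric", global_min=30, global_max=40),
    )


def record(schema, case_id, quarter, raw_qid, sensitive=(), drugs=()):
    return SRSRecord(case_id=case_id, quarter=quarter,
                     qid=make_qid(schema, raw_qid),
                     sensitive=frozenset(sensitive), drugs=frozenset(drugs))


def group_of(qid, member_qids, sensitive_sets=None):
    """Build a QIDGroup whose members carry the given qids (and optional
    sensitive sets); the generalized qid is supplied explicitly."""

    class _M:
        def __init__(self, qid, sens):
            self.qid = qid
            self.sensitive = frozenset(sens)
            self.is_new_case = True

    sens = sensitive_sets or [()] * len(member_qids)
    return QIDGroup(generalized_qid=qid,
                    members=[_M(q, s) for q, s in zip(member_qids, sens)])
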