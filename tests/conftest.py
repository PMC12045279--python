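import pytest

from incseq import (
    AlignmentHit,
    ResultTable,
    generate_protein_families,
    partition_batches,
    records_to_fasta,
)


def make_hit(
    query_id="q1",
    subject_id="s1",
    percent_identity=95.0,
    alignment_length=100,
    mismatches=5,
    gap_opens=0,
    q_start=1,
    q_end=100,
    s_start=1,
    s_end=100,
    evalue=1e-10,
    bit_score=150.0,
):
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        percent_identity=percent_identity,
        alignment_length=alignment_length,
        mismatches=mismatches,
        gap_opens=gap_opens,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        evalue=evalue,
        bit_score=bit_score,
    )


@pytest.fixture(scope="session")
def family_fixture():
    """The pinned synthetic study fixture: 4 classes x 5 families x 6 members,
    length 120, mutation rate 0.1, seed 17, 10 stratified batches; batch 1 is
    the query set and the other 9 form the growing database."""
    fams = generate_protein_families(
        n_classes=4, n_families_per_class=5, members_per_family=6,
        parent_length=120, mutation_rate=0.1, seed=17,
    )
    parts = partition_batches(fams.records, 10, strategy="stratified", seed=17)
    return {
        "families": fams,
        "query_records": parts[0],
        "batch_records": parts[1:],
        "query_fasta": records_to_fasta(parts[0]),
        "batch_fastas": [records_to_fasta(p) for p in parts[1:]],
        "full_db_fasta": records_to_fasta([r for p in parts[1:] for r in p]),
    }


def tables_field_equal(a: ResultTable, b: ResultTable, evalue_rtol=0.0) -> bool:
    if a.db_length != b.db_length or len(a) != len(b):
        return False
    for ha, hb in zip(a.hits, b.hits):
        if (
            ha.query_id != hb.query_id
            or ha.subject_id != hb.subject_id
            or ha.percent_identity != hb.percent_identity
            or ha.alignment_length != hb.alignment_length
            or ha.mismatches != hb.mismatches
            or ha.gap_opens != hb.gap_opens
            or (ha.q_start, ha.q_end, ha.s_start, ha.s_end)
            != (hb.q_start, hb.q_end, hb.s_start, hb.s_end)
            or ha.bit_score != hb.bit_score
        ):
            return False
        if evalue_rtol == 0.0:
            if ha.evalue != hb.evalue:
                return False
        else:
            scale = max(abs(ha.evalue), abs(hb.evalue), 1e-300)
            if abs(ha.evalue - hb.evalue) / scale > evalue_rtol:
                return False
    return True
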