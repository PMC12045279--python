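"""Concordance statistics, each checked against an independent brute-force
implementation on randomly generated small tables."""

import math

import numpy as np
import pytest

from incseq import (
    ResultTable,
    UndefinedResultError,
    average_hits_per_query,
    compare_tables,
    containment_fraction,
    dcg_scores,
    hit_and_evalue_ratios,
    kendall_concordance,
    pearson_concordance,
    top_hit_f1,
    zero_hit_proportion,
)
from incseq.merge_engine import sort_hits
from conftest import make_hit


def table(hits, db_length=1000):
    return ResultTable(hits=tuple(sort_hits(hits)), db_length=db_length)


def random_table(rng, n_queries=4, n_subjects=8, density=0.6):
    hits = []
    for q in range(n_queries):
        for s in range(n_subjects):
            if rng.random() < density:
                e = 10.0 ** rng.uniform(-40, -1)
                hits.append(
                    make_hit(
                        query_id=f"q{q}",
                        subject_id=f"s{s}",
                        evalue=e,
                        bit_score=float(np.round(-math.log10(e) * 3 + rng.integers(0, 5), 1)),
                    )
                )
    return table(hits)


# ---------------------------------------------------------------------------
# brute-force oracles (direct-formula implementations, no scipy/sklearn)


def oracle_pearson(xs, ys):
    n = len(xs)
    mx, my = sum(xs) / n, sum(ys) / n
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    vx = sum((x - mx) ** 2 for x in xs)
    vy = sum((y - my) ** 2 for y in ys)
    return cov / math.sqrt(vx * vy)


def oracle_tau_b(xs, ys):
    conc = disc = tx = ty = 0
    n = len(xs)
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = xs[i] - xs[j], ys[i] - ys[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    denom = math.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom


def oracle_dcg(gains):
    return sum(g / math.log2(i + 2) for i, g in enumerate(gains))


def shared_best_pairs(a, b):
    def best(t):
        out = {}
        for h in t.hits:
            k = (h.query_id, h.subject_id)
            if k not in out or (h.evalue, -h.bit_score) < (out[k].evalue, -out[k].bit_score):
                out[k] = h
        return out

    pa, pb = best(a), best(b)
    return pa, pb, sorted(pa.keys() & pb.keys())


# ---------------------------------------------------------------------------
# worked examples with frozen expected values


class TestExamples:
    def test_pearson_identical_tables(self):
        t = random_table(np.random.default_rng(0))
        assert pearson_concordance(t, t) == pytest.approx(1.0)

    def test_pearson_linear_relation_raw(self):
        """A constant multiplicative e-value shift — exactly what rescaling
        does — gives raw Pearson 1."""
        hits = [make_hit(subject_id=f"s{i}", evalue=10.0 ** -i) for i in range(1, 6)]
        scaled = [make_hit(subject_id=f"s{i}", evalue=3.7 * 10.0 ** -i) for i in range(1, 6)]
        assert pearson_concordance(table(hits), table(scaled), "raw") == pytest.approx(1.0)

    def test_pearson_three_point_example(self):
        # pairs (1,1),(2,2),(3,4): r = 0.98198..., frozen from the direct formula
        a = [make_hit(subject_id=f"s{i}", evalue=float(v)) for i, v in enumerate([1, 2, 3])]
        b = [make_hit(subject_id=f"s{i}", evalue=float(v)) for i, v in enumerate([1, 2, 4])]
        r = pearson_concordance(table(a), table(b), "raw")
        assert r == pytest.approx(0.9819805, abs=1e-6)

    def test_pearson_undefined_cases(self):
        one = table([make_hit()])
        with pytest.raises(UndefinedResultError):
            pearson_concordance(one, one)
        flat = table([make_hit(subject_id=f"s{i}", evalue=1e-8) for i in range(4)])
        with pytest.raises(UndefinedResultError):
            pearson_concordance(flat, flat, "raw")

    def test_kendall_identical_and_reversed(self):
        hits = [make_hit(subject_id=f"s{i}", evalue=10.0 ** -i, bit_score=float(i))
                for i in range(1, 5)]
        rev = [make_hit(subject_id=f"s{i}", evalue=10.0 ** (i - 6), bit_score=float(-i))
               for i in range(1, 5)]
        assert kendall_concordance(table(hits), table(hits)) == pytest.approx(1.0)
        assert kendall_concordance(table(hits), table(rev)) == pytest.approx(-1.0)

    def test_kendall_one_swap_example(self):
        # ranks [1,2,3,4] vs [1,3,2,4] -> tau = (5-1)/6, frozen by pair counting
        a = [make_hit(subject_id=f"s{i}", evalue=10.0 ** -(10 - i)) for i in range(4)]
        b_evalues = {0: 1e-10, 1: 1e-8, 2: 1e-9, 3: 1e-7}
        b = [make_hit(subject_id=f"s{i}", evalue=b_evalues[i]) for i in range(4)]
        assert kendall_concordance(table(a), table(b)) == pytest.approx(2 / 3, abs=1e-12)

    def test_kendall_no_contributing_query(self):
        with pytest.raises(UndefinedResultError):
            kendall_concordance(table([make_hit()]), table([make_hit()]))

    def test_dcg_example(self):
        # relevances [3, 2, 0] in rank order: 3 + 2/log2(3) = 4.26186
        hits = [make_hit(subject_id=f"s{i}", evalue=10.0 ** -(9 - i)) for i in range(3)]
        rel = {("q1", "s0"): 3.0, ("q1", "s1"): 2.0, ("q1", "s2"): 0.0}
        dcg, log_dcg, ndcg = dcg_scores(table(hits), rel, depth=10)["q1"]
        assert dcg == pytest.approx(4.2618595, abs=1e-6)
        assert log_dcg == pytest.approx(math.log1p(4.2618595), abs=1e-6)
        assert ndcg == pytest.approx(1.0)

    def test_ndcg_zero_when_no_relevant(self):
        hits = [make_hit(subject_id="sX")]
        assert dcg_scores(table(hits), {}, depth=5)["q1"] == (0.0, 0.0, 0.0)

    def test_negative_relevance_rejected(self):
        with pytest.raises(ValueError):
            dcg_scores(table([make_hit()]), {("q1", "s1"): -1.0})

    def test_containment_cases(self):
        a = table([make_hit(subject_id=f"s{i}") for i in range(4)])
        b_sub = table([make_hit(subject_id=f"s{i}") for i in range(3)])
        disjoint = table([make_hit(subject_id=f"x{i}") for i in range(3)])
        assert containment_fraction(b_sub, a) == 1.0
        assert containment_fraction(a, disjoint) == 0.0
        assert containment_fraction(a, b_sub) == 0.75
        assert containment_fraction(table([]), a) == 1.0  # vacuous

    def test_ratio_cases(self):
        hits = [make_hit(subject_id=f"s{i}", evalue=10.0 ** -(6 + i)) for i in range(4)]
        t = table(hits)
        assert hit_and_evalue_ratios(t, t) == (pytest.approx(1.0), pytest.approx(1.0))
        doubled = table([make_hit(subject_id=h.subject_id, evalue=2 * h.evalue) for h in hits])
        count_r, mean_r = hit_and_evalue_ratios(doubled, t)
        assert count_r == pytest.approx(1.0) and mean_r == pytest.approx(2.0)
        half = table(hits[:2])
        assert hit_and_evalue_ratios(t, half)[0] == pytest.approx(2.0)
        with pytest.raises(UndefinedResultError):
            hit_and_evalue_ratios(t, table([]))

    def test_zero_hit_proportion_cases(self):
        qids = {f"q{i}" for i in range(10)}
        hits = [make_hit(query_id=f"q{i}", evalue=1e-8) for i in range(8)]
        assert zero_hit_proportion(table(hits), qids) == pytest.approx(0.2)
        assert zero_hit_proportion(table(hits), {f"q{i}" for i in range(8)}) == 0.0
        assert zero_hit_proportion(table([]), qids) == 1.0
        with pytest.raises(ValueError):
            zero_hit_proportion(table([]), set())

    def test_average_hits_per_query_cases(self):
        qids = {f"q{i}" for i in range(10)}
        hits = [make_hit(query_id=f"q{i % 10}", subject_id=f"s{i}", evalue=1e-8)
                for i in range(30)]
        assert average_hits_per_query(table(hits), qids) == pytest.approx(3.0)
        assert average_hits_per_query(table([]), qids) == 0.0
        five = [make_hit(query_id="q0", subject_id=f"s{i}", evalue=1e-8) for i in range(5)]
        assert average_hits_per_query(table(five), {f"q{i}" for i in range(5)}) == 1.0


class TestTopHitF1:
    QL = {"q1": "A", "q2": "A", "q3": "B", "q4": "B"}
    SL = {"sA": "A", "sB": "B"}

    def test_perfect_classification(self):
        hits = [make_hit(query_id=q, subject_id="sA" if c == "A" else "sB")
                for q, c in self.QL.items()]
        assert top_hit_f1(table(hits), self.QL, self.SL) == 1.0

    def test_no_hits_scores_zero(self):
        assert top_hit_f1(table([]), self.QL, self.SL) == 0.0

    def test_two_class_confusion_hand_computed(self):
        """One error of each type: q2 (true A) -> B, q4 (true B) -> A.
        Both classes then have precision = recall = 0.5, so macro F1 = 0.5."""
        assign = {"q1": "sA", "q2": "sB", "q3": "sB", "q4": "sA"}
        hits = [make_hit(query_id=q, subject_id=s) for q, s in assign.items()]
        assert top_hit_f1(table(hits), self.QL, self.SL) == pytest.approx(0.5)

    def test_prediction_uses_lowest_evalue(self):
        hits = [
            make_hit(query_id="q1", subject_id="sB", evalue=1e-3),
            make_hit(query_id="q1", subject_id="sA", evalue=1e-9),
        ]
        ql = {"q1": "A"}
        assert top_hit_f1(table(hits), ql, self.SL) == 1.0

    def test_missing_label_names_id(self):
        hits = [make_hit(query_id="q1", subject_id="sZ")]
        with pytest.raises(KeyError, match="sZ"):
            top_hit_f1(table(hits), {"q1": "A"}, self.SL)


# ---------------------------------------------------------------------------
# randomized brute-force cross-checks (>= 100 tables per statistic)


@pytest.mark.parametrize("trial", range(100))
def test_statistics_match_brute_force(trial):
    rng = np.random.default_rng(9000 + trial)
    a = random_table(rng)
    b = random_table(rng)

    pa, pb, shared = shared_best_pairs(a, b)
    if len(shared) >= 2:
        xs = [-math.log10(pa[k].evalue) for k in shared]
        ys = [-math.log10(pb[k].evalue) for k in shared]
        if len(set(xs)) > 1 and len(set(ys)) > 1:
            assert pearson_concordance(a, b) == pytest.approx(
                oracle_pearson(xs, ys), abs=1e-10
            )

    # per-query tau-b, averaged
    by_query = {}
    for q, s in shared:
        by_query.setdefault(q, []).append(s)
    taus = []
    for q, subjects in by_query.items():
        if len(subjects) < 2:
            continue
        xs = [pa[(q, s)].evalue for s in subjects]
        ys = [pb[(q, s)].evalue for s in subjects]
        taus.append(oracle_tau_b(xs, ys))
    if taus:
        assert kendall_concordance(a, b) == pytest.approx(
            sum(taus) / len(taus), abs=1e-10
        )

    # DCG against the summation oracle, random relevance
    rel = {
        (h.query_id, h.subject_id): float(rng.integers(0, 4)) for h in a.hits
    }
    depth = 5
    scores = dcg_scores(a, rel, depth=depth)
    per_query_gains = {}
    for h in a.hits:  # table is sorted; take gains in rank order
        g = per_query_gains.setdefault(h.query_id, [])
        if len(g) < depth:
            g.append(rel[(h.query_id, h.subject_id)])
    for q, gains in per_query_gains.items():
        dcg, log_dcg, ndcg = scores[q]
        assert dcg == pytest.approx(oracle_dcg(gains), abs=1e-10)
        assert log_dcg == pytest.approx(math.log(1 + oracle_dcg(gains)), abs=1e-10)
        ideal = oracle_dcg(sorted(gains, reverse=True))
        assert ndcg == pytest.approx(dcg / ideal if ideal else 0.0, abs=1e-10)

    # containment / ratios / proportions via counting oracles
    pairs_a = {(h.query_id, h.subject_id) for h in a.hits}
    pairs_b = {(h.query_id, h.subject_id) for h in b.hits}
    if pairs_a:
        assert containment_fraction(a, b) == pytest.approx(
            len(pairs_a & pairs_b) / len(pairs_a)
        )
    thr = 1e-10
    below_a = [h for h in a.hits if h.evalue < thr]
    below_b = [h for h in b.hits if h.evalue < thr]
    if below_b:
        count_r, mean_r = hit_and_evalue_ratios(a, b, thr)
        assert count_r == pytest.approx(len(below_a) / len(below_b))
        mean_a = sum(h.evalue for h in below_a) / len(below_a) if below_a else 0.0
        mean_b = sum(h.evalue for h in below_b) / len(below_b)
        assert mean_r == pytest.approx(mean_a / mean_b)
    qids = {f"q{i}" for i in range(4)}
    hitless = qids - {h.query_id for h in below_a}
    assert zero_hit_proportion(a, qids, thr) == pytest.approx(len(hitless) / 4)
    assert average_hits_per_query(a, qids, thr) == pytest.approx(len(below_a) / 4)


def test_kendall_invariant_under_monotone_transform():
    rng = np.random.default_rng(77)
    a = random_table(rng)
    b = random_table(rng)
    # strictly monotone transform of b's e-values must not change tau
    transformed = ResultTable(
        hits=tuple(
            make_hit(query_id=h.query_id, subject_id=h.subject_id,
                     evalue=h.evalue ** 0.5 * 2.0, bit_score=h.bit_score)
            for h in b.hits
        ),
        db_length=b.db_length,
    )
    assert kendall_concordance(a, b) == pytest.approx(
        kendall_concordance(a, transformed), abs=1e-12
    )


def test_compare_tables_report_bounds():
    rng = np.random.default_rng(5)
    a, b = random_table(rng, density=0.9), random_table(rng, density=0.9)
    rep = compare_tables(a, b, threshold=1e-3)
    d = rep.as_dict()
    assert -1 <= d["pearson"] <= 1 and -1 <= d["kendall_tau"] <= 1
    assert 0 <= d["containment_fraction"] <= 1
    for k in ("zero_hit_proportion_a", "zero_hit_proportion_b",
              "mean_ndcg_a", "mean_ndcg_b"):
        assert 0 <= d[k] <= 1
    for k in ("hit_count_ratio", "mean_evalue_ratio", "mean_log_dcg_a",
              "mean_log_dcg_b", "avg_hits_per_query_a", "avg_hits_per_query_b"):
        assert d[k] >= 0
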