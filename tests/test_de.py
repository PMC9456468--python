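import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from keyreg import (
    build_six_lists,
    de_proteins,
    de_transcripts,
    empai,
    normalize_abundance,
)
from keyreg.de import DifferentialEntry, DifferentialList

from conftest import make_expression, make_peptides


# ---------------------------------------------------------------- oracle

def welch_bh_oracle(high, low, fold_threshold=2.0, alpha=0.05):
    """Brute-force re-computation: explicit loops, hand-coded Welch + BH."""
    genes = list(high.values.index)
    stats_rows = []
    for g in genes:
        h = [v for v in high.values.loc[g] if math.isfinite(v)]
        l = [v for v in low.values.loc[g] if math.isfinite(v)]
        if len(h) < 2 or len(l) < 2:
            continue
        mh = sum(h) / len(h)
        ml = sum(l) / len(l)
        vh = sum((x - mh) ** 2 for x in h) / (len(h) - 1)
        vl = sum((x - ml) ** 2 for x in l) / (len(l) - 1)
        se2 = vh / len(h) + vl / len(l)
        if se2 == 0:
            p = 1.0
        else:
            t = (mh - ml) / math.sqrt(se2)
            df = se2**2 / (
                (vh / len(h)) ** 2 / (len(h) - 1) + (vl / len(l)) ** 2 / (len(l) - 1)
            )
            p = 2.0 * stats.t.sf(abs(t), df)
        stats_rows.append((g, mh - ml, p))

    # Benjamini-Hochberg by hand
    n = len(stats_rows)
    order = sorted(range(n), key=lambda i: stats_rows[i][2])
    q = [0.0] * n
    prev = 1.0
    for rank_pos in range(n - 1, -1, -1):
        i = order[rank_pos]
        val = stats_rows[i][2] * n / (rank_pos + 1)
        prev = min(prev, val)
        q[i] = prev

    called = {}
    for (g, d, p), qi in zip(stats_rows, q):
        if abs(d) >= math.log2(fold_threshold) and qi <= alpha:
            called[g] = ("up" if d > 0 else "down", d, p, qi)
    return called


# ---------------------------------------------------------------- transcripts

def test_identical_matrices_give_empty_list():
    vals = np.random.default_rng(0).normal(0, 1, (50, 3))
    high = make_expression(vals, "high", "L")
    low = make_expression(vals, "low", "L")
    assert len(de_transcripts(high, low)) == 0


def test_planted_genes_recovered_and_match_oracle():
    # 500 null genes (sd 0.2) + 20 planted with log2 shift 2.0; the seed is
    # fixed so that all 20 planted genes clear the BH gate
    rng = np.random.default_rng(766)
    shift = np.zeros(520)
    shift[:20] = 2.0
    h = rng.normal(shift[:, None], 0.2, (520, 3))
    l = rng.normal(0.0, 0.2, (520, 3))
    high = make_expression(h, "high", "L")
    low = make_expression(l, "low", "L")
    result = de_transcripts(high, low)

    planted = {f"g{i}" for i in range(20)}
    assert result.entities == planted
    assert all(e.direction == "up" for e in result)

    oracle = welch_bh_oracle(high, low)
    assert set(oracle) == result.entities
    for e in result:
        direction, d, p, q = oracle[e.entity]
        assert e.direction == direction
        assert e.log2_fold_change == pytest.approx(d, abs=1e-12)
        assert e.p_value == pytest.approx(p, rel=1e-9)
        assert e.adj_p_value == pytest.approx(q, rel=1e-9)


def test_oracle_equivalence_on_random_matrices():
    rng = np.random.default_rng(42)
    for _ in range(100):
        shift = rng.choice([0.0, 1.5, -2.0], size=200, p=[0.8, 0.1, 0.1])
        h = rng.normal(shift[:, None], 0.4, (200, 3))
        l = rng.normal(0.0, 0.4, (200, 3))
        high = make_expression(h, "high")
        low = make_expression(l, "low")
        result = {e.entity: e.direction for e in de_transcripts(high, low)}
        oracle = {g: v[0] for g, v in welch_bh_oracle(high, low).items()}
        assert result == oracle


def test_subthreshold_fold_excluded_despite_tiny_p():
    rng = np.random.default_rng(3)
    h = rng.normal(0.8, 1e-6, (1, 3))  # exact log2 difference 0.8 => fold 1.74
    l = rng.normal(0.0, 1e-6, (1, 3))
    assert len(de_transcripts(make_expression(h, "high"), make_expression(l, "low"))) == 0


def test_mismatched_universe_rejected():
    h = make_expression(np.zeros((3, 3)), "high", genes=["a", "b", "c"])
    l = make_expression(np.zeros((3, 3)), "low", genes=["a", "b", "d"])
    with pytest.raises(ValueError, match="entity universe"):
        de_transcripts(h, l)


def test_single_replicate_rejected():
    with pytest.raises(ValueError, match="replicates"):
        make_expression(np.zeros((3, 1)), "high")


def test_gene_with_too_few_finite_values_skipped():
    h = np.zeros((2, 3))
    h[0] = [2.0, np.nan, np.nan]
    high = make_expression(h, "high")
    low = make_expression(np.zeros((2, 3)), "low")
    result = de_transcripts(high, low)  # must not raise
    assert "g0" not in result.entities


def test_null_bh_control():
    # global null: fraction of simulations with >= 1 called gene stays near alpha
    rng = np.random.default_rng(11)
    alpha = 0.05
    n_sims = 200
    hits = 0
    for _ in range(n_sims):
        h = rng.normal(0, 0.3, (1000, 3))
        l = rng.normal(0, 0.3, (1000, 3))
        if len(de_transcripts(make_expression(h, "high"), make_expression(l, "low"), alpha=alpha)):
            hits += 1
    bound = alpha + 3 * math.sqrt(alpha * (1 - alpha) / n_sims)
    assert hits / n_sims <= bound


# ---------------------------------------------------------------- emPAI

def test_empai_trivial_values():
    assert empai(0, 10) == 0.0
    assert empai(10, 10) == pytest.approx(9.0)
    assert empai(3, 10) == pytest.approx(0.99526, abs=1e-5)


def test_empai_invalid_observable():
    with pytest.raises(ValueError):
        empai(1, 0)


@given(observable=st.integers(1, 60), observed=st.integers(0, 59))
@settings(max_examples=60, deadline=None)
def test_empai_strictly_increasing_in_observed(observable, observed):
    assert empai(observed + 1, observable) > empai(observed, observable)
    assert empai(0, observable) == 0.0


# ---------------------------------------------------------------- normalization

def test_single_protein_normalizer_is_own_count():
    table = make_peptides([[5, 5, 5]], [5], "high")
    norm = normalize_abundance(table)
    assert np.allclose(norm.to_numpy(), 9.0 / 5.0)


def test_geometric_mean_normalizer():
    # observed counts (1, 2, 4): geometric mean exactly 2
    table = make_peptides([[1], [2], [4]], [10, 10, 10], "high")
    norm = normalize_abundance(table)
    for prot, obs in zip(["p0", "p1", "p2"], [1, 2, 4]):
        assert norm.loc[prot].iloc[0] == pytest.approx(empai(obs, 10) / 2.0, rel=1e-12)


def test_normalizer_scales_linearly_not_empai():
    t1 = make_peptides([[1], [2], [4]], [100, 100, 100], "high")
    t2 = make_peptides([[2], [4], [8]], [100, 100, 100], "high")
    n1 = normalize_abundance(t1).to_numpy()
    n2 = normalize_abundance(t2).to_numpy()
    # doubling the counts doubles the normalizer (geomean 2 -> 4) but the
    # emPAI numerator is nonlinear, so the result is not scale-invariant
    assert not np.allclose(n1, n2)
    assert np.exp(np.mean(np.log([2, 4, 8]))) == pytest.approx(4.0)


def test_all_zero_replicate_rejected():
    table = make_peptides([[0, 1], [0, 2]], [5, 5], "high")
    with pytest.raises(ValueError, match="normalizer undefined"):
        normalize_abundance(table)


# ---------------------------------------------------------------- proteins

def test_one_of_three_replicates_excluded():
    # p0 observed in exactly 1 of 3 high replicates and 0 low replicates
    high = make_peptides([[4, 0, 0], [5, 5, 5]], [10, 10], "high")
    low = make_peptides([[0, 0, 0], [5, 5, 5]], [10, 10], "low")
    result = de_proteins(high, low)
    assert "p0" not in {e.entity for e in result}


def test_presence_filter_and_unbounded():
    # p0 detected in 1/3 high reps only -> excluded; p1 comparable both
    # sides; p2 present high only -> unbounded up
    high = make_peptides([[4, 0, 0], [5, 5, 5], [6, 6, 6]], [10, 10, 10], "high")
    low = make_peptides([[0, 1, 0], [5, 5, 5], [0, 0, 0]], [10, 10, 10], "low")
    result = de_proteins(high, low)
    by_entity = {e.entity: e for e in result}
    assert "p0" not in by_entity
    assert "p1" not in by_entity  # same counts, similar normalizers
    assert by_entity["p2"].direction == "up"
    assert by_entity["p2"].unbounded
    assert math.isinf(by_entity["p2"].log2_fold_change)


def test_planted_ratio_matches_hand_computation():
    high = make_peptides([[8, 8, 8], [4, 4, 4]], [10, 10], "high")
    low = make_peptides([[4, 4, 4], [4, 4, 4]], [10, 10], "low")
    result = de_proteins(high, low)
    # hand computation of the normalized mean ratio for p0:
    # high replicate: geomean(8,4) = sqrt(32); low: geomean(4,4) = 4
    gm_h = math.sqrt(32.0)
    ratio = (empai(8, 10) / gm_h) / (empai(4, 10) / 4.0)
    by_entity = {e.entity: e for e in result}
    assert ratio > 2
    assert by_entity["p0"].log2_fold_change == pytest.approx(math.log2(ratio), rel=1e-12)
    assert by_entity["p0"].direction == "up"


def test_equal_tables_empty():
    obs = [[5, 6, 7], [3, 3, 3]]
    high = make_peptides(obs, [10, 10], "high")
    low = make_peptides(obs, [10, 10], "low")
    assert len(de_proteins(high, low)) == 0


def test_symmetry_swapping_populations():
    rng = np.random.default_rng(5)
    obs_h = rng.integers(0, 10, (30, 3))
    obs_l = rng.integers(0, 10, (30, 3))
    observable = rng.integers(5, 41, 30)
    high = make_peptides(obs_h, observable, "high")
    low = make_peptides(obs_l, observable, "low")
    fwd = {e.entity: e for e in de_proteins(high, low)}
    rev = {e.entity: e for e in de_proteins(low, high)}
    assert set(fwd) == set(rev)
    for ent, e in fwd.items():
        r = rev[ent]
        assert {e.direction, r.direction} == {"up", "down"} or e.log2_fold_change == 0
        if not e.unbounded:
            assert e.log2_fold_change == pytest.approx(-r.log2_fold_change, rel=1e-9)


def test_non_three_replicates_warns_and_generalizes(caplog):
    high = make_peptides([[8, 8, 8, 8], [2, 2, 2, 2]], [10, 10], "high")
    low = make_peptides([[2, 2, 2, 2], [2, 2, 2, 2]], [10, 10], "low")
    with caplog.at_level("WARNING"):
        result = de_proteins(high, low)
    assert "replicate count != 3" in caplog.text
    by_entity = {e.entity: e for e in result}
    assert by_entity["p0"].direction == "up"


# ---------------------------------------------------------------- six lists

def _dl(line, evidence, entities=()):
    entries = [
        DifferentialEntry(e, 1.0, "up", evidence) for e in entities
    ]
    return DifferentialList(line, evidence, entries)


def test_six_lists_cardinality_and_labels():
    per_line = {
        line: (_dl(line, "transcript", [f"t{line}"]), _dl(line, "protein"))
        for line in ("A", "B", "C")
    }
    lists = build_six_lists(per_line)
    assert len(lists) == 6
    assert len({dl.label for dl in lists}) == 6
    assert sum(1 for dl in lists if len(dl) == 0) == 3


def test_lists_are_independent_across_evidence():
    per_line = {
        "A": (_dl("A", "transcript", ["x"]), _dl("A", "protein", ["x"])),
        "B": (_dl("B", "transcript"), _dl("B", "protein")),
        "C": (_dl("C", "transcript"), _dl("C", "protein")),
    }
    lists = build_six_lists(per_line)
    containing = [dl.label for dl in lists if "x" in dl.entities]
    assert containing == ["A/transcript", "A/protein"]


def test_wrong_cell_line_count_rejected():
    per_line = {"A": (_dl("A", "transcript"), _dl("A", "protein"))}
    with pytest.raises(ValueError, match="3 cell lines"):
        build_six_lists(per_line)


def test_direction_consistency_enforced():
    with pytest.raises(ValueError):
        DifferentialEntry("x", -1.0, "up", "transcript")
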