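"""Synthetic score model, score-table IO, and GC-slope recovery."""

import numpy as np
import pytest

from hexamask.affinity_model import (
    EDR_LIKE_PARAMS,
    ScoreModelParams,
    ScoreRecord,
    ScoreTable,
    fit_gc_slope,
    load_score_table,
    save_score_table,
    simulate_scores,
)
from hexamask.duplex_space import canonicalize, enumerate_duplexes


@pytest.fixture(scope="module")
def dimers():
    return enumerate_duplexes(2)


def test_degenerate_model_constant(dimers):
    params = ScoreModelParams(beta0=-30.0, beta_gc=0.0, sigma=0.0)
    table = simulate_scores(params, dimers)
    assert all(rec.score == -30.0 for rec in table)


def test_noiseless_model_is_function_of_gc_and_mask(hexamer_duplexes):
    params = ScoreModelParams(beta0=-31.76, beta_gc=-0.925, sigma=0.0)
    table = simulate_scores(params, hexamer_duplexes)
    by_key = {}
    for rec in table:
        key = (rec.duplex.gc_count, rec.duplex.mask)
        by_key.setdefault(key, set()).add(rec.score)
    assert all(len(scores) == 1 for scores in by_key.values())
    # expected all-GC score ~ -37.3 under the default calibration
    all_gc = next(r for r in table if r.duplex.gc_count == 6 and r.duplex.mask == "SSSSSS")
    assert all_gc.score == pytest.approx(-31.76 + 6 * -0.925)


def test_monotone_gc_trend_noiseless(hexamer_duplexes):
    params = ScoreModelParams(beta0=-31.76, beta_gc=-0.925, sigma=0.0)
    table = simulate_scores(params, hexamer_duplexes)
    means = {}
    for rec in table:
        means.setdefault(rec.duplex.gc_count, []).append(rec.score)
    mean_by_gc = [np.mean(means[g]) for g in range(7)]
    assert all(a > b for a, b in zip(mean_by_gc, mean_by_gc[1:]))


def test_determinism_and_seed_sensitivity(dimers):
    p = ScoreModelParams(sigma=2.5, seed=42)
    t1 = simulate_scores(p, dimers)
    t2 = simulate_scores(p, dimers)
    assert [r.score for r in t1] == [r.score for r in t2]
    t3 = simulate_scores(ScoreModelParams(sigma=2.5, seed=43), dimers)
    assert [r.score for r in t1] != [r.score for r in t3]


def test_order_independence(dimers):
    p = ScoreModelParams(sigma=2.5, seed=1)
    a = simulate_scores(p, dimers)
    b = simulate_scores(p, list(reversed(dimers)))
    assert {r.duplex: r.score for r in a} == {r.duplex: r.score for r in b}


def test_mask_effects_applied_and_validated(dimers):
    p = ScoreModelParams(beta0=0.0, beta_gc=0.0, sigma=0.0,
                         mask_effects={"WW": -5.0})
    table = simulate_scores(p, dimers)
    for rec in table:
        expected = -5.0 if rec.duplex.mask == "WW" else 0.0
        assert rec.score == expected
    bad = ScoreModelParams(mask_effects={"WWW": -1.0})
    with pytest.raises(ValueError, match="length"):
        simulate_scores(bad, dimers)


def test_score_record_consistency_enforced():
    with pytest.raises(ValueError):
        ScoreRecord("X", "GAGTGG", canonicalize("AAAAAA"), -1.0)
    with pytest.raises(ValueError, match="finite"):
        ScoreRecord("X", "GAGTGG", canonicalize("GAGTGG"), float("nan"))


def test_duplicate_duplex_rejected():
    recs = [
        ScoreRecord("X", "GAGTGG", canonicalize("GAGTGG"), -44.71),
        ScoreRecord("X", "CCACTC", canonicalize("CCACTC"), -40.0),
    ]
    with pytest.raises(ValueError, match="reverse complement"):
        ScoreTable(peptide_id="X", records=recs)


def test_load_save_round_trip(tmp_path, dimers):
    table = simulate_scores(ScoreModelParams(sigma=1.0, seed=5), dimers, "PEP")
    path = tmp_path / "scores.tsv"
    save_score_table(table, path)
    loaded = load_score_table(path)
    assert loaded.peptide_id == "PEP"
    assert [(r.written_strand, r.score) for r in loaded] == [
        (r.written_strand, r.score) for r in table
    ]


def test_load_rejects_duplicates_and_malformed(tmp_path):
    p = tmp_path / "dup.tsv"
    p.write_text("peptide\tstrand\tscore\nX\tGAGTGG\t-44.71\nX\tCCACTC\t-40.0\n")
    with pytest.raises(ValueError, match="GAGTGG"):
        load_score_table(p)
    p2 = tmp_path / "bad.tsv"
    p2.write_text("peptide\tstrand\tscore\nX\tGAGTGG\toops\n")
    with pytest.raises(ValueError, match="line|:2"):
        load_score_table(p2)
    p3 = tmp_path / "empty.tsv"
    p3.write_text("")
    with pytest.raises(ValueError, match="empty"):
        load_score_table(p3)


def test_complete_table_flag(tmp_path, hexamer_duplexes):
    table = simulate_scores(ScoreModelParams(sigma=0.0), hexamer_duplexes)
    assert len(table) == 2080 and table.is_complete
    partial = ScoreTable("SIM", table.records[:100])
    assert not partial.is_complete


def test_gc_slope_noiseless_recovery(hexamer_duplexes):
    table = simulate_scores(
        ScoreModelParams(beta0=-30.0, beta_gc=-0.9, sigma=0.0), hexamer_duplexes
    )
    slope, se = fit_gc_slope(table)
    assert slope == pytest.approx(-0.9, abs=1e-12)
    assert se == pytest.approx(0.0, abs=1e-8)  # floating-point residual only


def test_gc_slope_constant_table(dimers):
    table = simulate_scores(ScoreModelParams(beta0=-5.0, beta_gc=0.0, sigma=0.0), dimers)
    slope, se = fit_gc_slope(table)
    assert slope == pytest.approx(0.0, abs=1e-12)


def test_gc_slope_degenerate_design():
    recs = [
        ScoreRecord("X", s, canonicalize(s), -1.0)
        for s in ("AAAAAA", "AAAAAT")  # only GC counts {0}
    ]
    with pytest.raises(ValueError, match="distinct GC"):
        fit_gc_slope(ScoreTable("X", recs))


def test_parameter_recovery_across_seeds(hexamer_duplexes):
    """Mean fitted slope near truth; spread consistent with the OLS SE."""
    true_slope = EDR_LIKE_PARAMS.beta_gc
    slopes, ses = [], []
    for seed in range(20):
        p = ScoreModelParams(beta0=EDR_LIKE_PARAMS.beta0, beta_gc=true_slope,
                             sigma=EDR_LIKE_PARAMS.sigma, seed=seed)
        slope, se = fit_gc_slope(simulate_scores(p, hexamer_duplexes))
        slopes.append(slope)
        ses.append(se)
    assert abs(np.mean(slopes) - true_slope) < 0.05
    # analytic OLS SE: sigma / sqrt(n * var(gc))
    gc = np.array([d.gc_count for d in hexamer_duplexes], dtype=float)
    analytic_se = EDR_LIKE_PARAMS.sigma / np.sqrt(len(gc) * gc.var())
    assert abs(np.std(slopes, ddof=1) - analytic_se) / analytic_se < 0.5
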