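"""Population pipeline: library runs, distributions, correlation, screens."""

import numpy as np
import pandas as pd
import pytest

from icnsim import membrane as mb
from icnsim import population as pop
from icnsim import synthetic as syn
from icnsim import transcriptome as tx
from icnsim.channels import GENES, TRANSCRIPTS
from icnsim.spikes import ClassificationRules


@pytest.fixture(scope="module")
def fixture_results():
    return pop.run_library(syn.fixture_genotypes())


def test_run_library_flags_non_excitable(fixture_results):
    t = fixture_results.table
    assert t.loc["F1", "status"] == "non-excitable"  # leak-only
    assert t.loc["F2", "status"] == "non-excitable"  # Na only
    assert (t.loc[["F3", "F4", "F5"], "status"] == "ok").all()


def test_run_library_results_keyed_uniquely(fixture_results):
    assert fixture_results.table.index.is_unique


def test_run_library_is_reproducible(fixture_results):
    again = pop.run_library(syn.fixture_genotypes())
    pd.testing.assert_frame_equal(fixture_results.table, again.table)


def test_run_library_rejects_empty_library():
    with pytest.raises(ValueError):
        pop.run_library(tx.GenotypeLibrary(genotypes=[], threshold=15.0))


def test_fixture_phenotypes_span_regimes(fixture_results):
    t = fixture_results.table
    assert t.loc["F3", "phenotype"] == "tonic"  # Na + Kv3.1
    assert t.loc["F4", "phenotype"] == "phasic"  # Na + full K set
    assert t.loc["F5", "phenotype"] in ("phasic", "phasic-to-tonic", "tonic")


# ---------------------------------------------------------------------------
# Distribution arithmetic
# ---------------------------------------------------------------------------

def make_results(phenos_counts):
    rows = []
    for i, (ph, n) in enumerate(phenos_counts):
        rows.append(
            {"label": f"T{i+1}", "count": n, "excitable": True, "status": "ok", "phenotype": ph}
        )
    table = pd.DataFrame(rows).set_index("label")
    return pop.PopulationResults(table=table, amplitudes=(0.1, 0.3, 0.5), rules=ClassificationRules())


def test_firing_distribution_genotype_weighting():
    res = make_results([("phasic", 5), ("phasic", 1), ("tonic", 9), ("phasic-to-tonic", 2)])
    dist = pop.firing_distribution(res)
    assert dist["phasic"] == pytest.approx(50.0)
    assert dist["tonic"] == pytest.approx(25.0)
    assert dist["phasic-to-tonic"] == pytest.approx(25.0)
    assert dist["tonic-to-phasic"] == 0.0
    assert dist.sum() == pytest.approx(100.0, abs=1e-9)


def test_firing_distribution_cell_weighting_uses_counts():
    res = make_results([("phasic", 5), ("tonic", 15)])
    dist = pop.firing_distribution(res, weighting="cell")
    assert dist["phasic"] == pytest.approx(25.0)
    assert dist["tonic"] == pytest.approx(75.0)


def test_firing_distribution_filters_artifact_genotypes():
    res = make_results([("phasic", 1), ("other", 1), ("tonic", 1)])
    dist = pop.firing_distribution(res)
    assert dist["phasic"] == pytest.approx(50.0)


def test_weightings_coincide_for_equal_counts():
    res = make_results([("phasic", 3), ("tonic", 3), ("tonic-to-phasic", 3)])
    assert np.allclose(pop.firing_distribution(res), pop.firing_distribution(res, "cell"))


def test_firing_distribution_invalid_weighting():
    with pytest.raises(ValueError):
        pop.firing_distribution(make_results([("phasic", 1)]), weighting="neuron")


# ---------------------------------------------------------------------------
# Conductance-expression correlation
# ---------------------------------------------------------------------------

def proportional_ct(conductances: mb.ConductanceSet, n=6):
    """Ct matrix in which expression folds exactly equal conductance folds."""
    g_ref = conductances.for_gene("Cacna1a")
    ct_ref = 14.0
    cols = {}
    for t in TRANSCRIPTS:
        gene = "Kcna1+ab1" if t in ("Kcna1", "Kcnab1") else t
        fold = conductances.for_gene(gene) / g_ref
        cols[t] = ct_ref - np.log2(fold)
    ids = [f"n{i}" for i in range(n)]
    frame = pd.DataFrame({t: [v] * n for t, v in cols.items()}, index=ids)[list(TRANSCRIPTS)]
    return tx.CtMatrix(ct=frame, metadata=pd.DataFrame(index=ids))


def test_correlation_is_one_for_proportional_tables():
    cs = mb.ConductanceSet()
    res = pop.conductance_expression_correlation(proportional_ct(cs), cs)
    assert res["r2"] == pytest.approx(1.0, abs=1e-9)
    assert res["table"].loc["Cacna1a", "conductance_fold"] == pytest.approx(1.0)
    assert res["table"].loc["Cacna1a", "expression_fold"] == pytest.approx(1.0)


def test_correlation_invariant_to_global_conductance_rescale(small_ct):
    cs = mb.ConductanceSet()
    scaled = mb.ConductanceSet(gbars={g: 3.0 * v for g, v in cs.gbars.items()})
    r1 = pop.conductance_expression_correlation(small_ct, cs)["r2"]
    r2 = pop.conductance_expression_correlation(small_ct, scaled)["r2"]
    assert r1 == pytest.approx(r2, rel=1e-12)


def test_correlation_excludes_requested_genes(small_ct):
    res = pop.conductance_expression_correlation(small_ct)
    assert "Hcn3" not in res["table"].index
    assert "Cacna1b" not in res["table"].index


def test_correlation_requires_expressed_reference():
    ids = ["n0"]
    frame = pd.DataFrame(tx.CT_SENTINEL, index=ids, columns=list(TRANSCRIPTS))
    ctm = tx.CtMatrix(ct=frame, metadata=pd.DataFrame(index=ids))
    with pytest.raises(ValueError, match="reference"):
        pop.conductance_expression_correlation(ctm)


# ---------------------------------------------------------------------------
# Sensitivity analyses
# ---------------------------------------------------------------------------

def test_oat_zero_perturbation_gives_zero_deltas(tonic_model):
    deltas = pop.sensitivity_oat(tonic_model, "Kcnc1", perturbation=0.0, amplitude=0.3)
    assert np.allclose(deltas.to_numpy(), 0.0, equal_nan=False)


def test_oat_zeroing_sodium_silences_the_model(tonic_model):
    deltas = pop.sensitivity_oat(tonic_model, "Scn1a", perturbation=1.0, amplitude=0.3)
    base_freq = -deltas.loc["down", "d_frequency_hz"]
    assert base_freq > 0  # the unperturbed model was firing
    # gbar_Na = 0 removes the spike mechanism entirely


def test_oat_is_deterministic(tonic_model):
    d1 = pop.sensitivity_oat(tonic_model, "Kcnc1", 0.2, 0.3)
    d2 = pop.sensitivity_oat(tonic_model, "Kcnc1", 0.2, 0.3)
    pd.testing.assert_frame_equal(d1, d2)


def test_oat_rejects_unknown_gene(tonic_model):
    with pytest.raises(KeyError):
        pop.sensitivity_oat(tonic_model, "Hcn1", 0.2, 0.3)


def test_hinf_zero_change_matches_baseline():
    lib = syn.fixture_genotypes()
    base = pop.firing_distribution(pop.run_library(lib, measure_passive=False))
    same = pop.perturb_na_hinf(lib, 0.0)
    assert np.allclose(base, same)


# ---------------------------------------------------------------------------
# Parameter screen
# ---------------------------------------------------------------------------

POINT_RANGES = {g: (v, v) for g, v in mb._DEFAULT_GBARS.items()}


def test_screen_degenerate_ranges_give_identical_decisions():
    res = pop.parameter_screen(POINT_RANGES, n_samples=3, seed=1)
    assert res["log"]["accepted"].nunique() == 1
    assert res["log"]["reason"].nunique(dropna=False) == 1


def test_screen_is_seed_deterministic():
    ranges = {"Scn1a": (0.05, 0.1), "Kcnc1": (0.01, 0.03)}
    r1 = pop.parameter_screen(ranges, n_samples=4, seed=42)
    r2 = pop.parameter_screen(ranges, n_samples=4, seed=42)
    assert [c.gbars for c in r1["accepted"]] == [c.gbars for c in r2["accepted"]]
    pd.testing.assert_frame_equal(r1["log"], r2["log"])


def test_screen_widening_rin_band_grows_accepted_set():
    ranges = {"Scn1a": (0.05, 0.1), "Kcnc1": (0.01, 0.03), "Kcnj3": (0.001, 0.006)}
    tight = pop.parameter_screen(
        ranges, n_samples=6, seed=7, criteria=pop.ScreenCriteria(rin_band=(40.0, 45.0))
    )
    wide = pop.parameter_screen(
        ranges, n_samples=6, seed=7, criteria=pop.ScreenCriteria(rin_band=(30.0, 300.0))
    )
    tight_ids = {i for i, row in tight["log"].iterrows() if row["accepted"]}
    wide_ids = {i for i, row in wide["log"].iterrows() if row["accepted"]}
    assert tight_ids <= wide_ids


def test_screen_validates_inputs():
    with pytest.raises(ValueError):
        pop.parameter_screen({"Scn1a": (0.1, 0.05)}, n_samples=2, seed=0)
    with pytest.raises(ValueError):
        pop.parameter_screen(POINT_RANGES, n_samples=0, seed=0)
    with pytest.raises(ValueError):
        pop.ScreenCriteria(rin_band=(300.0, 40.0))
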