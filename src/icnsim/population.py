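"""Library-wide simulation, firing statistics and parameter analyses.

Orchestrates the end-to-end pipeline: every excitable genotype in a library
is assembled into a membrane model, its leak is balanced against the
passive-property constraints, an ordered current-clamp sweep is simulated
and classified, and the resulting phenotype distribution, f-I relationships,
conductance-expression correlation, sensitivity analyses and the
rejection-sampling conductance screen are computed on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import channels as ch
from . import membrane as mb
from .spikes import (
    ClassificationRules,
    classify_genotype,
    classify_trace,
    detect_spikes,
    fi_slope,
    spike_metrics,
    PHENOTYPES,
)
from .transcriptome import CtMatrix, GenotypeLibrary, binarize

__all__ = [
    "PopulationResults",
    "ScreenCriteria",
    "run_library",
    "firing_distribution",
    "conductance_expression_correlation",
    "sensitivity_oat",
    "perturb_na_hinf",
    "parameter_screen",
    "DEFAULT_AMPLITUDES",
]

DEFAULT_AMPLITUDES = (0.1, 0.3, 0.5)  # nA, the published sweep


@dataclass
class PopulationResults:
    """Per-genotype classification table plus the sweep that produced it."""

    table: pd.DataFrame  # indexed by genotype label
    amplitudes: tuple
    rules: ClassificationRules

    def classified(self) -> pd.DataFrame:
        """Rows that enter firing statistics: excitable, simulated OK and
        with a non-artifact phenotype."""
        t = self.table
        return t[(t["status"] == "ok") & t["phenotype"].isin(PHENOTYPES[:4])]


@dataclass(frozen=True)
class ScreenCriteria:
    """Acceptance bands of the passive-property rejection screen."""

    rmp_band: tuple = (-66.0, -56.0)
    rin_band: tuple = (40.0, 300.0)  # MOhm
    rheobase_band: tuple = (0.02, 0.08)  # nA
    epas_band: tuple = (-80.0, -50.0)  # mV

    def __post_init__(self):
        for b in (self.rmp_band, self.rin_band, self.rheobase_band, self.epas_band):
            if b[0] >= b[1]:
                raise ValueError("criteria bands must be well-ordered")


def _simulate_genotype(model, amplitudes, rules, protocol):
    classes, freqs = [], []
    for amp in amplitudes:
        proto = replace(protocol, amplitude_na=amp)
        trace = mb.simulate(model, proto)
        train = detect_spikes(trace.t, trace.vm, model.config.spike_threshold)
        cls = classify_trace(trace.t, trace.vm, train, proto.delay_ms, proto.duration_ms, rules)
        met = spike_metrics(trace.t, trace.vm, train, proto.delay_ms, proto.duration_ms)
        classes.append(cls)
        freqs.append(met.frequency)
    return classes, freqs


def run_library(
    library: GenotypeLibrary,
    conductances: mb.ConductanceSet | None = None,
    amplitudes: Sequence[float] = DEFAULT_AMPLITUDES,
    config: mb.SimulationConfig | None = None,
    rules: ClassificationRules = ClassificationRules(),
    target_rmp: float = -61.0,
    protocol: mb.StimulusProtocol | None = None,
    channel_overrides: Mapping[str, ch.ChannelSpec] | None = None,
    measure_passive: bool = True,
) -> PopulationResults:
    """Simulate and classify every genotype of a library.

    Deterministic: genotypes are processed in label order and every
    simulation is fixed-step.  Per-genotype failures (leak rejection,
    spontaneous activity, numerical blow-up) are recorded in the ``status``
    column rather than raised.
    """
    if len(library) == 0:
        raise ValueError("empty genotype library")
    conductances = conductances or mb.ConductanceSet()
    protocol = protocol or mb.StimulusProtocol()
    amplitudes = tuple(amplitudes)
    rows = []
    for gt in library:
        row = {
            "label": gt.label,
            "count": gt.count,
            "excitable": gt.excitable,
            "n_channels": len(gt.channels),
            "status": "ok",
            "phenotype": None,
            "e_pas": np.nan,
            "g_pas": np.nan,
            "rmp": np.nan,
            "rin": np.nan,
        }
        for amp in amplitudes:
            row[f"class_{amp}"] = None
            row[f"freq_{amp}"] = np.nan
        if not gt.excitable:
            row["status"] = "non-excitable"
            rows.append(row)
            continue
        try:
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                model = mb.build_model(
                    gt, conductances=conductances, config=config, label=gt.label,
                    channel_overrides=channel_overrides,
                )
            model = model.with_leak(mb.tune_leak(model, target_rmp=target_rmp))
            row["e_pas"] = model.leak.e_pas
            row["g_pas"] = model.leak.g_pas
            if measure_passive:
                try:
                    row["rmp"] = mb.measure_rmp(model)
                    row["rin"] = mb.measure_rin(model)
                except mb.SpontaneousActivityError:
                    pass  # classification below will surface the artifact
            classes, freqs = _simulate_genotype(model, amplitudes, rules, protocol)
        except mb.ModelRejectedError:
            row["status"] = "rejected"
            rows.append(row)
            continue
        except mb.SimulationBlowupError:
            row["status"] = "blowup"
            rows.append(row)
            continue
        for amp, cls, f in zip(amplitudes, classes, freqs):
            row[f"class_{amp}"] = cls
            row[f"freq_{amp}"] = f
        row["phenotype"] = classify_genotype(classes)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("label")
    return PopulationResults(table=table, amplitudes=amplitudes, rules=rules)


def firing_distribution(results: PopulationResults, weighting: str = "genotype") -> pd.Series:
    """Percentage of each phenotype among cleanly classified genotypes.

    ``weighting='genotype'`` counts each genotype once; ``'cell'`` weights
    by occurrence counts.  Artifact/other genotypes are excluded, mirroring
    the filtering of stray artificial firing patterns from the statistics.
    """
    if weighting not in ("genotype", "cell"):
        raise ValueError("weighting must be 'genotype' or 'cell'")
    good = results.classified()
    if good.empty:
        raise ValueError("no classified genotypes after artifact filtering")
    w = good["count"] if weighting == "cell" else pd.Series(1.0, index=good.index)
    agg = w.groupby(good["phenotype"]).sum()
    pct = 100.0 * agg / agg.sum()
    return pct.reindex(PHENOTYPES[:4], fill_value=0.0)


def fi_curves(results: PopulationResults) -> tuple[pd.DataFrame, float]:
    """f-I points of all tonic traces plus the pooled OLS slope (Hz/nA)."""
    pts = []
    for label, row in results.classified().iterrows():
        for amp in results.amplitudes:
            if row[f"class_{amp}"] == "tonic":
                pts.append({"label": label, "amplitude_na": amp, "frequency_hz": row[f"freq_{amp}"]})
    df = pd.DataFrame(pts)
    slope = fi_slope(df["amplitude_na"], df["frequency_hz"]) if len(df) >= 2 else float("nan")
    return df, slope


# ---------------------------------------------------------------------------
# Conductance-expression correlation
# ---------------------------------------------------------------------------

# channel gene -> transcript carrying its expression level
_EXPRESSION_TRANSCRIPT = {"Kcna1+ab1": "Kcna1"}


def conductance_expression_correlation(
    ctm: CtMatrix,
    conductances: mb.ConductanceSet | None = None,
    reference: str = "Cacna1a",
    exclusions: Sequence[str] = ("Hcn3", "Cacna1b"),
    threshold: float = 15.0,
) -> dict:
    """Correlate model conductance ratios with transcriptomic expression ratios.

    Conductance fold = gbar_gene / gbar_ref.  Expression level of a gene is
    the mean of ``2**(mean Ct_ref - Ct)`` over the neurons expressing it
    (Ct at or below the threshold), i.e. the mean expression relative to
    the reference gene's average; folds are log10-transformed on both axes
    before the Pearson correlation.  Returns the per-gene table, R^2 and
    the fitted line.
    """
    conductances = conductances or mb.ConductanceSet()
    presence = binarize(ctm, threshold)
    ref_t = _EXPRESSION_TRANSCRIPT.get(reference, reference)
    ref_mask = presence[ref_t]
    if not ref_mask.any():
        raise ValueError(f"reference gene {reference} unexpressed in every neuron")
    ct_ref_mean = float(ctm.ct.loc[ref_mask, ref_t].mean())
    g_ref = conductances.for_gene(reference)

    rows = []
    for gene in ch.GENES:
        if gene in exclusions:
            continue
        transcript = _EXPRESSION_TRANSCRIPT.get(gene, gene)
        mask = presence[transcript]
        if not mask.any():
            continue
        expr_fold = float(np.mean(2.0 ** (ct_ref_mean - ctm.ct.loc[mask, transcript])))
        rows.append(
            {
                "gene": gene,
                "conductance_fold": conductances.for_gene(gene) / g_ref,
                "expression_fold": expr_fold,
                "n_expressing": int(mask.sum()),
            }
        )
    table = pd.DataFrame(rows).set_index("gene")
    x = np.log10(table["expression_fold"])
    y = np.log10(table["conductance_fold"])
    fit = stats.linregress(x, y)
    return {"table": table, "r2": float(fit.rvalue**2), "slope": float(fit.slope), "intercept": float(fit.intercept)}


# ---------------------------------------------------------------------------
# Sensitivity analyses
# ---------------------------------------------------------------------------

def sensitivity_oat(
    model: mb.NeuronModel,
    gene: str,
    perturbation: float = 0.2,
    amplitude: float = 0.3,
    protocol: mb.StimulusProtocol | None = None,
) -> pd.DataFrame:
    """One-at-a-time conductance perturbation at a fixed stimulus.

    Scales the gene's gbar by (1 +/- perturbation) and reports the change in
    firing frequency, AP peak, maximum hyperpolarization and FWHM relative
    to the unperturbed model.  Deterministic and bit-reproducible.
    """
    if gene not in model.channel_genes:
        raise KeyError(f"gene {gene!r} not in model genotype")
    if perturbation < 0 or (1.0 - perturbation) < 0:
        raise ValueError("perturbed conductance would be negative")
    protocol = protocol or mb.StimulusProtocol(amplitude_na=amplitude)
    protocol = replace(protocol, amplitude_na=amplitude)

    def run(m):
        trace = mb.simulate(m, protocol)
        train = detect_spikes(trace.t, trace.vm, m.config.spike_threshold)
        return spike_metrics(trace.t, trace.vm, train, protocol.delay_ms, protocol.duration_ms)

    base = run(model)
    rows = {}
    for name, factor in (("up", 1.0 + perturbation), ("down", 1.0 - perturbation)):
        pert = run(model.with_conductances(model.conductances.scaled(gene, factor)))
        rows[name] = {
            "d_frequency_hz": pert.frequency - base.frequency,
            "d_ap_peak_mv": pert.ap_peak - base.ap_peak,
            "d_max_hyperpolarization_mv": pert.max_hyperpolarization - base.max_hyperpolarization,
            "d_fwhm_ms": pert.fwhm - base.fwhm,
        }
    return pd.DataFrame(rows).T


def perturb_na_hinf(
    library: GenotypeLibrary,
    slope_change: float,
    weighting: str = "genotype",
    **run_kwargs,
) -> pd.Series:
    """Phenotype distribution with the Nav1.1 h_inf slope constant rescaled.

    ``slope_change`` is a fraction (+0.2 scales the 6.2 mV slope constant by
    1.2, shallowing inactivation).  Returns the firing distribution of the
    re-classified library.
    """
    factor = 1.0 + slope_change
    overrides = {"Scn1a": ch.scale_inf_slope(ch.get_channel("Scn1a"), "h", factor)} if slope_change else None
    results = run_library(library, channel_overrides=overrides, measure_passive=False, **run_kwargs)
    return firing_distribution(results, weighting=weighting)


# ---------------------------------------------------------------------------
# Rejection-sampling conductance screen
# ---------------------------------------------------------------------------

def parameter_screen(
    ranges: Mapping[str, tuple],
    n_samples: int,
    seed: int,
    criteria: ScreenCriteria = ScreenCriteria(),
    genotype=None,
    conductances: mb.ConductanceSet | None = None,
    phi_range: tuple | None = None,
    config: mb.SimulationConfig | None = None,
) -> dict:
    """Uniformly sample conductance sets and keep the physiologically tenable.

    Each sample draws gbar values from the per-gene ranges (and optionally
    the Kv3.1 mix fraction), assembles the genotype (default: all 14
    channels), balances the leak, and is accepted iff RMP, input impedance,
    rheobase and the leak reversal all fall inside the criteria bands.
    Returns accepted :class:`ConductanceSet` objects plus a per-criterion
    rejection log.  Seeded and deterministic.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    for gene, (lo, hi) in ranges.items():
        if lo < 0 or hi < lo:
            raise ValueError(f"bad range for {gene}: {(lo, hi)}")
    rng = np.random.default_rng(seed)
    base = conductances or mb.ConductanceSet()
    genes = tuple(genotype) if genotype is not None else ch.GENES
    accepted = []
    log = []
    import warnings as _w

    for i in range(n_samples):
        gbars = dict(base.gbars)
        for gene, (lo, hi) in ranges.items():
            gbars[gene] = float(rng.uniform(lo, hi))
        phi = float(rng.uniform(*phi_range)) if phi_range else base.phi_kcnc1
        cs = mb.ConductanceSet(gbars=gbars, phi_kcnc1=phi)
        entry = {"sample": i, "accepted": False, "reason": None}
        try:
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                model = mb.build_model(genes, conductances=cs, config=config, label=f"S{i}")
            model = model.with_leak(mb.tune_leak(model, band=criteria.epas_band))
            rmp = mb.measure_rmp(model)
            if not criteria.rmp_band[0] <= rmp <= criteria.rmp_band[1]:
                entry["reason"] = "rmp"
                log.append(entry)
                continue
            rin = mb.measure_rin(model)
            if not criteria.rin_band[0] <= rin <= criteria.rin_band[1]:
                entry["reason"] = "rin"
                log.append(entry)
                continue
            rheo = mb.find_rheobase(model, search_range=(0.0, 2 * criteria.rheobase_band[1]))
            if rheo is None or not criteria.rheobase_band[0] <= rheo <= criteria.rheobase_band[1]:
                entry["reason"] = "rheobase"
                log.append(entry)
                continue
        except mb.ModelRejectedError:
            entry["reason"] = "epas"
            log.append(entry)
            continue
        except (mb.SpontaneousActivityError, mb.SimulationBlowupError):
            entry["reason"] = "artifact"
            log.append(entry)
            continue
        entry["accepted"] = True
        accepted.append(cs)
        log.append(entry)
    return {"accepted": accepted, "log": pd.DataFrame(log).set_index("sample")}
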