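"""Synthetic single-neuron Ct matrices with the structure the pipeline assumes.

Each transcript is expressed in a neuron with a configurable probability;
expressed transcripts draw a low Ct from a truncated Gaussian, unexpressed
ones a high Ct floored above the working threshold range, so a cutoff of 15
cycles discriminates the two components.  A configurable fraction of
neurons is guaranteed to express the Na+ channel plus at least one K+
channel (the excitability requirement the study's threshold choice was made
to satisfy), and per-neuron metadata (animal, sex, SAN projection) mimics a
four-animal design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .channels import TRANSCRIPTS
from .transcriptome import (
    CT_SENTINEL,
    CtMatrix,
    Genotype,
    GenotypeLibrary,
    K_TRANSCRIPTS,
)

__all__ = ["SyntheticCtParams", "DEFAULT_EXPRESSION_PROBS", "generate_ct", "fixture_genotypes"]

# Per-transcript expression probabilities, chosen once to echo the
# qualitative expression spectrum of porcine RAGP neurons: the Na+ channel
# and the Kv1.1 complex are near-ubiquitous, Kv3.1 is the most expressed K+
# channel, HCN1/3 and three of the Ca2+ channels (a, d, g) are rare.
# Probabilities are polarized (most genes near 0 or 1) so that a few
# hundred neurons concentrate into a realistic mix of common genotypes and
# singletons rather than being almost all unique.
DEFAULT_EXPRESSION_PROBS: dict = {
    "Scn1a": 0.97,
    "Hcn1": 0.15,
    "Hcn2": 0.85,
    "Hcn3": 0.10,
    "Hcn4": 0.15,
    "Kcna1": 0.93,
    "Kcnab1": 0.88,
    "Kcnc1": 0.95,
    "Kcnj3": 0.85,
    "Cacna1a": 0.03,
    "Cacna1b": 0.20,
    "Cacna1c": 0.88,
    "Cacna1d": 0.04,
    "Cacna1g": 0.03,
    "Cacna1i": 0.15,
}

# Mean expressed Ct per transcript (cycles; lower = more abundant).  Real
# single-neuron panels show a per-gene expression gradient -- abundant
# channels amplify several cycles earlier -- and this gradient is what the
# conductance-expression comparison rests on, so the generator reproduces
# it qualitatively.
DEFAULT_EXPRESSED_MEANS: dict = {
    "Scn1a": 9.0,
    "Hcn1": 12.5,
    "Hcn2": 11.5,
    "Hcn3": 13.0,
    "Hcn4": 12.5,
    "Kcna1": 10.5,
    "Kcnab1": 11.0,
    "Kcnc1": 10.0,
    "Kcnj3": 12.0,
    "Cacna1a": 13.5,
    "Cacna1b": 13.0,
    "Cacna1c": 11.0,
    "Cacna1d": 13.0,
    "Cacna1g": 13.5,
    "Cacna1i": 12.5,
}


@dataclass(frozen=True)
class SyntheticCtParams:
    """Knobs of the synthetic qPCR generator.

    The expressed-Ct component is truncated at the binarization threshold
    (15 cycles) so that the empirical presence rate converges to the
    configured probability; the unexpressed component is floored above the
    13-17 threshold range.  ``coexpression`` optionally couples pairs:
    ``(a, b, p)`` re-draws b as expressed with probability p wherever a is
    expressed (default independent).
    """

    n_neurons: int = 405
    expression_probs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_EXPRESSION_PROBS))
    expressed_means: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_EXPRESSED_MEANS))
    expressed_mean: float = 12.0  # fallback for transcripts without a per-gene mean
    expressed_sd: float = 2.0
    expressed_range: tuple = (5.0, 15.0)
    unexpressed_mean: float = 25.0
    unexpressed_sd: float = 3.0
    unexpressed_range: tuple = (18.0, 40.0)
    undetected_prob: float = 0.15  # unexpressed cells reported as sentinel
    excitable_fraction: float = 0.9
    n_animals: int = 4
    san_prob: float = 0.5
    coexpression: tuple = ()

    def __post_init__(self):
        for t, p in self.expression_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"expression probability for {t} outside [0, 1]")
        if self.n_neurons <= 0:
            raise ValueError("need at least one neuron")
        if not 0.0 <= self.excitable_fraction <= 1.0:
            raise ValueError("excitable_fraction must lie in [0, 1]")
        if self.expressed_range[1] > self.unexpressed_range[0]:
            raise ValueError("expressed and unexpressed Ct ranges must be separated")


def _trunc_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def generate_ct(params: SyntheticCtParams = SyntheticCtParams(), seed: int = 0) -> CtMatrix:
    """Draw a seeded, reproducible synthetic Ct matrix."""
    rng = np.random.default_rng(seed)
    n = params.n_neurons
    probs = np.array([params.expression_probs.get(t, 0.0) for t in TRANSCRIPTS])
    expressed = rng.random((n, len(TRANSCRIPTS))) < probs

    # optional pairwise co-expression coupling
    tidx = {t: i for i, t in enumerate(TRANSCRIPTS)}
    for a, b, p in params.coexpression:
        mask = expressed[:, tidx[a]]
        expressed[mask, tidx[b]] = rng.random(int(mask.sum())) < p

    # guarantee excitability for a configurable fraction of neurons
    n_force = int(round(params.excitable_fraction * n))
    forced = rng.permutation(n)[:n_force]
    expressed[forced, tidx["Scn1a"]] = True
    k_idx = [tidx[k] for k in K_TRANSCRIPTS]
    k_probs = np.array([params.expression_probs.get(k, 0.0) for k in K_TRANSCRIPTS])
    k_probs = k_probs / k_probs.sum() if k_probs.sum() > 0 else np.full(len(k_idx), 1 / len(k_idx))
    for i in forced:
        if not expressed[i, k_idx].any():
            expressed[i, rng.choice(k_idx, p=k_probs)] = True

    ct = np.empty((n, len(TRANSCRIPTS)))
    for j, t in enumerate(TRANSCRIPTS):
        col = expressed[:, j]
        mean = params.expressed_means.get(t, params.expressed_mean)
        ct[col, j] = _trunc_normal(rng, mean, params.expressed_sd, *params.expressed_range, int(col.sum()))
    n_un = int((~expressed).sum())
    un = _trunc_normal(rng, params.unexpressed_mean, params.unexpressed_sd, *params.unexpressed_range, n_un)
    un[rng.random(n_un) < params.undetected_prob] = CT_SENTINEL
    ct[~expressed] = un

    ids = [f"N{i + 1:04d}" for i in range(n)]
    animals = [f"A{(i % params.n_animals) + 1}" for i in rng.integers(0, params.n_animals, n)]
    # first half of the animals male, second half female
    sex = ["M" if int(a[1:]) <= params.n_animals // 2 else "F" for a in animals]
    meta = pd.DataFrame(
        {
            "animal": animals,
            "sex": sex,
            "san": rng.random(n) < params.san_prob,
        },
        index=ids,
    )
    frame = pd.DataFrame(np.round(ct, 3), index=ids, columns=list(TRANSCRIPTS))
    return CtMatrix(ct=frame, metadata=meta, sentinel=CT_SENTINEL)


def write_ct(ctm: CtMatrix, path) -> None:
    """Write a Ct matrix in the delimited format ``load_ct`` reads."""
    out = pd.concat([ctm.ct, ctm.metadata], axis=1)
    out.index.name = "neuron"
    out.to_csv(path)


def fixture_genotypes() -> GenotypeLibrary:
    """Deterministic mini-library spanning silent to tonic regimes.

    Five genotypes: leak-only, Na-only (non-excitable by the K+ guard),
    Na + Kv3.1 (tonic-like), Na + the full K+ set (phasic-like) and the
    complete 15-transcript pattern (14 channels after the Kcna1/Kcnab1
    merge).
    """
    patterns = {
        "leak-only": (),
        "na-only": ("Scn1a",),
        "na-kv31": ("Scn1a", "Kcnc1"),
        "na-kset": ("Scn1a", "Kcna1", "Kcnab1", "Kcnc1", "Kcnj3"),
        "full": tuple(TRANSCRIPTS),
    }
    genotypes = []
    for i, (_, genes) in enumerate(patterns.items()):
        presence = tuple(t in genes for t in TRANSCRIPTS)
        genotypes.append(Genotype(presence=presence, label=f"F{i + 1}", count=1))
    return GenotypeLibrary(genotypes=genotypes, threshold=15.0, source="fixture")
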