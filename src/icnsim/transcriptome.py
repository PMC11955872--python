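"""Ct-matrix handling: QC, binarization and neuronal-genotype collapse.

High-throughput qPCR reports a cycle threshold (Ct) per neuron and
transcript; low Ct means high expression.  Expression is binarized with an
inclusive cutoff (Ct <= 15 cycles by default) and each unique presence
pattern over the 15-transcript panel defines a *neuronal genotype*.  The
Kcna1/Kcnab1 pair collapses to a single channel: with the beta1 subunit the
delayed rectifier gains fast inactivation, without it the channel is
non-inactivating, and the subunit alone makes no channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .channels import TRANSCRIPTS

__all__ = [
    "CT_SENTINEL",
    "DEFAULT_THRESHOLD",
    "CtMatrix",
    "Genotype",
    "GenotypeLibrary",
    "load_ct",
    "qc_filter",
    "binarize",
    "channels_from_presence",
    "collapse_genotypes",
    "common_genotypes",
    "threshold_sweep",
]

CT_SENTINEL = 40.0  # undetected-transcript marker; above any threshold in use
DEFAULT_THRESHOLD = 15.0
METADATA_COLUMNS = ("animal", "sex", "san")

K_TRANSCRIPTS = ("Kcna1", "Kcnc1", "Kcnj3")  # potassium alpha subunits


@dataclass
class CtMatrix:
    """Neurons x transcripts cycle-threshold values plus per-neuron metadata."""

    ct: pd.DataFrame
    metadata: pd.DataFrame
    sentinel: float = CT_SENTINEL

    def __post_init__(self):
        missing = [t for t in TRANSCRIPTS if t not in self.ct.columns]
        if missing:
            raise ValueError(f"Ct matrix lacks required transcript columns: {missing}")
        vals = self.ct[list(TRANSCRIPTS)].to_numpy(dtype=float)
        if np.any(~np.isnan(vals) & (vals <= 0)):
            raise ValueError("Ct values must be positive (or the sentinel)")
        if not self.metadata.index.equals(self.ct.index):
            raise ValueError("metadata index must match the Ct matrix index")

    @property
    def n_neurons(self) -> int:
        return len(self.ct)

    def subset(self, index) -> "CtMatrix":
        return CtMatrix(ct=self.ct.loc[index], metadata=self.metadata.loc[index], sentinel=self.sentinel)


def load_ct(path, sep: str = ",", sentinel: float = CT_SENTINEL) -> CtMatrix:
    """Read a delimited Ct matrix (neurons as rows, transcripts as columns).

    Optional metadata columns ``animal``, ``sex`` and ``san`` are split off;
    other unknown columns are reported with a warning and dropped.  Missing
    cells become the sentinel (undetected).
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    missing = [t for t in TRANSCRIPTS if t not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required transcript column(s) {missing}")
    meta_cols = [c for c in METADATA_COLUMNS if c in df.columns]
    unknown = [c for c in df.columns if c not in TRANSCRIPTS and c not in meta_cols]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {unknown}", stacklevel=2)
    ct = df[list(TRANSCRIPTS)].apply(pd.to_numeric, errors="coerce")
    bad = ct.isna() & df[list(TRANSCRIPTS)].notna()
    if bad.to_numpy().any():
        raise ValueError(f"{path}: non-numeric Ct values present")
    ct = ct.fillna(sentinel)
    meta = df[meta_cols].copy() if meta_cols else pd.DataFrame(index=df.index)
    return CtMatrix(ct=ct, metadata=meta, sentinel=sentinel)


def qc_filter(
    ctm: CtMatrix,
    exclude_animals: Sequence = (),
    require_na: bool = False,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[CtMatrix, dict]:
    """Remove neurons from excluded animals and, optionally, Na-negative ones.

    Returns the filtered matrix and a report of removal counts.
    """
    keep = pd.Series(True, index=ctm.ct.index)
    removed_by_animal: dict = {}
    if len(exclude_animals) and "animal" in ctm.metadata.columns:
        for a in exclude_animals:
            mask = ctm.metadata["animal"] == a
            removed_by_animal[a] = int(mask.sum())
            keep &= ~mask
    removed_na = 0
    if require_na:
        has_na = ctm.ct["Scn1a"] <= threshold
        removed_na = int((keep & ~has_na).sum())
        keep &= has_na
    if not keep.any():
        raise ValueError("QC filter removed every neuron")
    report = {
        "n_in": ctm.n_neurons,
        "n_out": int(keep.sum()),
        "removed_by_animal": removed_by_animal,
        "removed_na_negative": removed_na,
    }
    return ctm.subset(keep[keep].index), report


def binarize(ctm: CtMatrix, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Presence matrix: transcript expressed iff Ct <= threshold (inclusive)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return ctm.ct[list(TRANSCRIPTS)] <= threshold


def channels_from_presence(presence: Mapping[str, bool]) -> tuple[str, ...]:
    """Collapse a transcript presence pattern to the channel-gene set.

    Applies the Kcna1/Kcnab1 merge: both -> inactivating 'Kcna1+ab1';
    Kcna1 alone -> non-inactivating 'Kcna1'; Kcnab1 alone -> no channel.
    """
    out = []
    for t in TRANSCRIPTS:
        if t in ("Kcna1", "Kcnab1"):
            continue
        if presence.get(t, False):
            out.append(t)
    if presence.get("Kcna1", False):
        out.append("Kcna1+ab1" if presence.get("Kcnab1", False) else "Kcna1")
    return tuple(sorted(out))


@dataclass(frozen=True)
class Genotype:
    """A unique transcript presence pattern with its derived channel set."""

    presence: tuple  # booleans in TRANSCRIPTS order
    label: str
    count: int = 1

    def __post_init__(self):
        if len(self.presence) != len(TRANSCRIPTS):
            raise ValueError("presence vector must cover all 15 transcripts")

    @property
    def presence_map(self) -> dict:
        return dict(zip(TRANSCRIPTS, self.presence))

    @property
    def channels(self) -> tuple:
        return channels_from_presence(self.presence_map)

    @property
    def excitable(self) -> bool:
        """Na+ channel plus at least one K+ channel present."""
        p = self.presence_map
        return p["Scn1a"] and any(p[k] for k in K_TRANSCRIPTS)

    @property
    def pattern(self) -> str:
        return "".join("1" if x else "0" for x in self.presence)


@dataclass
class GenotypeLibrary:
    """Unique genotypes with occurrence counts at a given Ct threshold."""

    genotypes: list
    threshold: float
    source: str = ""

    def __post_init__(self):
        pats = [g.pattern for g in self.genotypes]
        if len(set(pats)) != len(pats):
            raise ValueError("genotypes must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.genotypes)

    @property
    def n_cells(self) -> int:
        return sum(g.count for g in self.genotypes)

    def __iter__(self):
        return iter(self.genotypes)

    def get(self, label: str) -> Genotype:
        for g in self.genotypes:
            if g.label == label:
                return g
        raise KeyError(label)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "label": g.label,
                "count": g.count,
                "excitable": g.excitable,
                "n_channels": len(g.channels),
                "pattern": g.pattern,
                **g.presence_map,
            }
            for g in self.genotypes
        ]
        return pd.DataFrame(rows).set_index("label")

    def binary_map(self) -> pd.DataFrame:
        """Genotypes x transcripts boolean map, transcripts ordered by
        overall (cell-weighted) frequency, most common first."""
        df = pd.DataFrame([g.presence_map for g in self.genotypes], index=[g.label for g in self.genotypes])
        weights = np.array([g.count for g in self.genotypes])
        freq = (df.to_numpy() * weights[:, None]).sum(axis=0)
        order = [t for _, t in sorted(zip(freq, TRANSCRIPTS), key=lambda p: (-p[0], p[1]))]
        return df[order]


def collapse_genotypes(presence: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD, source: str = "") -> GenotypeLibrary:
    """Collapse a binarized matrix into unique genotypes with counts.

    Labels T1, T2, ... are assigned deterministically: by count descending,
    ties broken by the lexicographic presence pattern.
    """
    pats = presence[list(TRANSCRIPTS)].apply(lambda row: "".join("1" if v else "0" for v in row), axis=1)
    counts = pats.value_counts()
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    genotypes = [
        Genotype(presence=tuple(c == "1" for c in pat), label=f"T{i + 1}", count=int(n))
        for i, (pat, n) in enumerate(ordered)
    ]
    return GenotypeLibrary(genotypes=genotypes, threshold=threshold, source=source)


def common_genotypes(library: GenotypeLibrary, min_count: int = 10) -> GenotypeLibrary:
    """Genotypes with more than ``min_count`` occurrences."""
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    subset = [g for g in library.genotypes if g.count > min_count]
    return GenotypeLibrary(genotypes=subset, threshold=library.threshold, source=library.source)


def threshold_sweep(
    ctm: CtMatrix,
    thresholds: Sequence[float] = (13, 14, 15, 16, 17),
    reference: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Genotype turnover as the Ct cutoff moves around the reference.

    For each threshold: the genotype count, the percentage of genotypes not
    present at the reference threshold, and the fraction of cells those new
    genotypes cover.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be ordered")
    ref_lib = collapse_genotypes(binarize(ctm, reference), reference)
    ref_patterns = {g.pattern for g in ref_lib}
    rows = []
    for thr in thresholds:
        lib = collapse_genotypes(binarize(ctm, thr), thr)
        new = [g for g in lib if g.pattern not in ref_patterns]
        rows.append(
            {
                "threshold": thr,
                "n_genotypes": len(lib),
                "n_cells": lib.n_cells,
                "pct_new_genotypes": 100.0 * len(new) / len(lib) if len(lib) else 0.0,
                "pct_cells_in_new": 100.0 * sum(g.count for g in new) / lib.n_cells if lib.n_cells else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("threshold")
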