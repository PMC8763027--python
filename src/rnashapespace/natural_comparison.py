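"""Comparing natural shape frequencies against G-sampled predictions.

The headline analysis: fold a database of natural (or synthetic) sequences
of one length, build its shape spectrum ``f_p``, and ask how well the
G-sampled spectrum ``f_pG`` predicts it — by coverage (what fraction of
natural shapes the random sample also found), by Pearson correlation of
log-frequencies over shared shapes, and by per-shape binomial tests for
shapes over- or under-represented relative to the G-sampling null (e.g.
database deposition bias toward much-studied molecules such as tRNA).

Lengths are analyzed separately; spectra from different (L, level) are
never pooled.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, TextIO, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from Bio import SeqIO

from .folding import Folder
from .gsampling import ShapeSpectrum, build_spectrum
from .secondary_structure import SequenceError, normalize_sequence

logger = logging.getLogger(__name__)


class EmptyDatasetError(ValueError):
    """No sequences survived filtering."""


@dataclass
class NaturalDataset:
    """Deduplicated, length-homogeneous set of natural-style sequences."""

    sequences: list[str]
    source_label: str
    L: int

    def __post_init__(self) -> None:
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("dataset contains duplicate sequences")
        for s in self.sequences:
            if len(s) != self.L:
                raise ValueError(f"sequence of length {len(s)} in L={self.L} dataset")

    def __len__(self) -> int:
        return len(self.sequences)


def load_natural(source: Union[str, TextIO], L: int,
                 source_label: Optional[str] = None) -> NaturalDataset:
    """Load a FASTA file into a :class:`NaturalDataset`.

    Records are normalized (T->U, uppercased); records with characters
    outside the alphabet or of the wrong length are skipped and counted;
    exact duplicate sequences are discarded, keeping first occurrence.
    """
    label = source_label or (source if isinstance(source, str) else "<stream>")
    seen: set[str] = set()
    kept: list[str] = []
    n_bad_alphabet = n_bad_length = n_duplicate = 0
    for record in SeqIO.parse(source, "fasta"):
        try:
            seq = str(normalize_sequence(str(record.seq)))
        except SequenceError:
            n_bad_alphabet += 1
            continue
        if len(seq) != L:
            n_bad_length += 1
            continue
        if seq in seen:
            n_duplicate += 1
            continue
        seen.add(seq)
        kept.append(seq)
    logger.info(
        "load_natural(%s, L=%d): kept %d, skipped %d bad-alphabet, "
        "%d wrong-length, %d duplicates",
        label, L, len(kept), n_bad_alphabet, n_bad_length, n_duplicate,
    )
    if not kept:
        raise EmptyDatasetError(f"no length-{L} sequences in {label}")
    return NaturalDataset(kept, label, L)


def natural_spectrum(ds: NaturalDataset, folder: Folder,
                     level: int) -> ShapeSpectrum:
    """Shape spectrum of a natural dataset (n_samples = dataset size).

    Each deduplicated sequence contributes one count to its shape, so a
    shape reached by many distinct sequences is counted that many times.
    """
    if not ds.sequences:
        raise EmptyDatasetError("empty dataset")
    spec = build_spectrum(iter(ds.sequences), folder, level, L=ds.L)
    spec.metadata["source"] = ds.source_label
    return spec


@dataclass(frozen=True)
class Outlier:
    shape: str
    observed: int
    expected: float
    p_adjusted: float
    direction: str  # "over" | "under"


@dataclass
class ComparisonResult:
    """Agreement between a natural spectrum f_p and a G-sample f_pG."""

    n_natural_shapes: int
    n_gsample_shapes: int
    shared_shapes: list[str]
    coverage: float
    pearson_r: Optional[float]
    p_value: Optional[float]
    n_correlated: int
    n_excluded: int  # natural shapes left out of the correlation
    outliers: list[Outlier] = field(default_factory=list)

    @property
    def correlation_defined(self) -> bool:
        return self.pearson_r is not None

    def to_dict(self) -> dict:
        return {
            "n_natural_shapes": self.n_natural_shapes,
            "n_gsample_shapes": self.n_gsample_shapes,
            "n_shared": len(self.shared_shapes),
            "coverage": self.coverage,
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
            "n_correlated": self.n_correlated,
            "n_excluded": self.n_excluded,
            "outliers": [vars(o) for o in self.outliers],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def compare_spectra(natural: ShapeSpectrum, gsample: ShapeSpectrum,
                    min_natural_count: int = 1,
                    alpha: float = 0.05) -> ComparisonResult:
    """Coverage, log–log Pearson correlation, and outliers of f_p vs f_pG.

    The correlation is computed on (log10 f_p, log10 f_pG) over shapes
    observed in both spectra with at least ``min_natural_count`` natural
    counts (no pseudocounts; the number of natural shapes excluded this way
    is reported).  Fewer than 3 such shapes leaves the correlation
    undefined (``pearson_r is None``); coverage is reported regardless.
    """
    if (natural.L, natural.level) != (gsample.L, gsample.level):
        raise ValueError("spectra must share L and level")
    nat_shapes = set(natural.counts)
    gs_shapes = set(gsample.counts)
    shared = sorted(nat_shapes & gs_shapes)
    coverage = len(shared) / len(nat_shapes) if nat_shapes else 0.0

    corr_shapes = [s for s in shared
                   if natural.counts[s] >= min_natural_count]
    n_excluded = len(nat_shapes) - len(corr_shapes)
    if len(corr_shapes) >= 3:
        x = np.log10([natural.frequency(s) for s in corr_shapes])
        y = np.log10([gsample.frequency(s) for s in corr_shapes])
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r = p = None  # degenerate: constant frequencies
        else:
            res = stats.pearsonr(x, y)
            r, p = float(res.statistic), float(res.pvalue)
    else:
        r = p = None

    outliers = overrepresentation_test(natural, gsample, alpha=alpha)
    return ComparisonResult(
        n_natural_shapes=len(nat_shapes),
        n_gsample_shapes=len(gs_shapes),
        shared_shapes=shared,
        coverage=coverage,
        pearson_r=r,
        p_value=p,
        n_correlated=len(corr_shapes),
        n_excluded=n_excluded,
        outliers=outliers,
    )


def enrichment_table(natural: ShapeSpectrum,
                     gsample: ShapeSpectrum) -> pd.DataFrame:
    """Per-shared-shape table of f_p, f_pG, CI, binomial p and BH-adjusted p.

    Each natural count k (out of N sequences) is tested two-sided against a
    Binomial(N, f_pG) null; Benjamini–Hochberg adjustment is applied across
    all shared shapes.
    """
    if (natural.L, natural.level) != (gsample.L, gsample.level):
        raise ValueError("spectra must share L and level")
    shared = sorted(set(natural.counts) & set(gsample.counts))
    if not shared:
        return pd.DataFrame(columns=[
            "shape", "natural_count", "f_p", "f_pG", "expected",
            "ci_low", "ci_high", "p_raw", "p_adjusted", "direction",
        ])
    N = natural.n_samples
    rows = []
    for s in shared:
        k = natural.counts[s]
        f_pg = gsample.frequency(s)
        p_raw = stats.binomtest(k, N, f_pg, alternative="two-sided").pvalue
        lo, hi = natural.wilson_ci(s)
        rows.append({
            "shape": s, "natural_count": k, "f_p": k / N, "f_pG": f_pg,
            "expected": N * f_pg, "ci_low": lo, "ci_high": hi,
            "p_raw": float(p_raw),
            "direction": "over" if k > N * f_pg else "under",
        })
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p_raw"].to_numpy(), method="fdr_bh")[1]
    return df[["shape", "natural_count", "f_p", "f_pG", "expected",
               "ci_low", "ci_high", "p_raw", "p_adjusted", "direction"]]


def overrepresentation_test(natural: ShapeSpectrum, gsample: ShapeSpectrum,
                            alpha: float = 0.05) -> list[Outlier]:
    """Shapes whose natural counts deviate from the G-sampling null.

    Exact two-sided binomial test per shared shape against success
    probability f_pG, BH-corrected; returns shapes with adjusted p < alpha.
    """
    df = enrichment_table(natural, gsample)
    flagged = df[df["p_adjusted"] < alpha]
    return [
        Outlier(row.shape, int(row.natural_count), float(row.expected),
                float(row.p_adjusted), row.direction)
        for row in flagged.itertuples(index=False)
    ]
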