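"""Elementary-binding-unit (3-mer) frequency profiling and tissue-selectivity
testing.

Each recovered 9-mer peptide is decomposed into its overlapping 3-mers
(seven windows).  By default every distinct peptide contributes each of its
*distinct* 3-mers once, so deep resequencing of one clone does not inflate a
motif; a read-weighted mode is available.  Tissue selectivity of a motif is a
one-sided Fisher's exact test on the 2x2 table of (motif, all other motifs) x
(tissue, normalizer), corrected per tissue/normalizer family with
Benjamini-Hochberg, and called selective at adjusted p < 0.05 and fold > 2.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .processing import PeptideRecord

DEFAULT_MIN_FREQUENCY_PCT = 0.0125  # 1/8000, as a percentage
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_FOLD = 2.0
NORMALIZATION_SCHEMES = ("library", "all_other_tissues", "serum")


@dataclass
class MotifCountTable:
    tissue_id: str
    counts: pd.Series  # motif -> occurrence count
    weighting: str  # "unique_peptide" | "read_weighted"

    @property
    def total_motifs(self) -> int:
        return int(self.counts.sum())


@dataclass
class MotifFrequencyProfile:
    tissue_id: str
    frequencies: pd.Series  # motif -> % of total motifs


@dataclass
class ClusteredProfileMatrix:
    """Low-frequency-filtered motif x tissue percentage matrix with Ward
    linkages and leaf orders for heatmap rendering."""

    matrix: pd.DataFrame  # rows motifs, columns tissues
    motif_linkage: np.ndarray | None
    tissue_linkage: np.ndarray | None
    motif_order: list[int]
    tissue_order: list[int]


def extract_motifs(peptide: str, k: int = 3) -> list[str]:
    """All overlapping k-mer windows of a peptide, in order."""
    if len(peptide) < k:
        raise ValueError(f"peptide {peptide!r} shorter than k={k}")
    return [peptide[i : i + k] for i in range(len(peptide) - k + 1)]


def count_motifs(
    peptides: Iterable[PeptideRecord | str],
    weighting: str = "unique_peptide",
    k: int = 3,
    tissue_id: str = "",
) -> MotifCountTable:
    """Tally overlapping k-mers across a peptide collection.

    ``unique_peptide``: each distinct peptide contributes each of its distinct
    k-mers once.  ``read_weighted``: contributions are multiplied by the
    peptide's read count.
    """
    if weighting not in ("unique_peptide", "read_weighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    counts: Counter[str] = Counter()
    n = 0
    for rec in peptides:
        n += 1
        seq = rec if isinstance(rec, str) else rec.peptide
        weight = 1 if weighting == "unique_peptide" or isinstance(rec, str) else rec.read_count
        for motif in set(extract_motifs(seq, k)):
            counts[motif] += weight
    if n == 0:
        raise ValueError("empty peptide collection")
    series = pd.Series(counts, dtype=int).sort_index()
    return MotifCountTable(tissue_id=tissue_id, counts=series, weighting=weighting)


def motif_frequencies(table: MotifCountTable) -> MotifFrequencyProfile:
    """Convert counts to percentages of the tissue's total motif tally."""
    total = table.total_motifs
    if total <= 0:
        raise ValueError("motif table has no counts")
    return MotifFrequencyProfile(
        tissue_id=table.tissue_id, frequencies=100.0 * table.counts / total
    )


def cluster_profiles(
    profiles: Sequence[MotifFrequencyProfile],
    min_frequency: float = DEFAULT_MIN_FREQUENCY_PCT,
) -> ClusteredProfileMatrix:
    """Low-frequency filter and two-way Ward clustering of tissue profiles.

    Motifs below ``min_frequency`` percent in *every* sample are removed;
    the remaining percentage matrix is clustered on both axes with Ward
    linkage on Euclidean distance.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to cluster")
    matrix = pd.DataFrame(
        {p.tissue_id: p.frequencies for p in profiles}
    ).fillna(0.0)
    keep = matrix.max(axis=1) >= min_frequency
    matrix = matrix.loc[keep]
    if matrix.empty:
        raise ValueError("all motifs fall below the frequency filter")
    if matrix.shape[0] >= 2:
        motif_link = linkage(matrix.values, method="ward")
        motif_order = leaves_list(motif_link).tolist()
    else:
        motif_link, motif_order = None, [0]
    tissue_link = linkage(matrix.values.T, method="ward")
    tissue_order = leaves_list(tissue_link).tolist()
    return ClusteredProfileMatrix(matrix, motif_link, tissue_link, motif_order, tissue_order)


def fisher_one_sided_p(a, b, c, d) -> np.ndarray:
    """One-sided (enrichment) Fisher p for 2x2 tables [[a, b], [c, d]].

    Equals the hypergeometric tail P(X >= a) with all margins fixed; accepts
    scalars or aligned arrays.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    if np.any(a < 0) or np.any(b < 0) or np.any(c < 0) or np.any(d < 0):
        raise ValueError("contingency cells must be non-negative")
    total = a + b + c + d
    return hypergeom.sf(a - 1, total, a + c, a + b)


def pool_counts(tables: Sequence[MotifCountTable], tissue_id: str = "pooled") -> MotifCountTable:
    """Sum raw motif counts across samples (the 'all other tissues' normalizer)."""
    if not tables:
        raise ValueError("nothing to pool")
    weighting = tables[0].weighting
    summed = pd.Series(dtype=int)
    for t in tables:
        summed = summed.add(t.counts, fill_value=0)
    return MotifCountTable(tissue_id, summed.astype(int).sort_index(), weighting)


def fisher_enrichment(
    tissue_table: MotifCountTable,
    norm_table: MotifCountTable,
    scheme: str = "library",
) -> pd.DataFrame:
    """Per-motif fold change and one-sided Fisher p of a tissue against a
    normalizing sample.

    The 2x2 table for motif m is [[a, Ta - a], [c, Tn - c]] with a, c the
    motif's counts and Ta, Tn the total motif tallies.  Fold change is the
    frequency ratio; when the normalizer count is zero, a 0.5 pseudocount is
    added to both numerator cells for the fold only (p always uses raw counts).
    Motifs absent from both samples are skipped.
    """
    if scheme not in NORMALIZATION_SCHEMES:
        raise ValueError(f"scheme must be one of {NORMALIZATION_SCHEMES}")
    total_tissue = tissue_table.total_motifs
    total_norm = norm_table.total_motifs
    if total_tissue <= 0 or total_norm <= 0:
        raise ValueError("both tables must be non-empty")
    motifs = tissue_table.counts.index.union(norm_table.counts.index)
    a = tissue_table.counts.reindex(motifs, fill_value=0).to_numpy(dtype=np.int64)
    c = norm_table.counts.reindex(motifs, fill_value=0).to_numpy(dtype=np.int64)
    present = (a + c) > 0
    motifs, a, c = motifs[present], a[present], c[present]
    b = total_tissue - a
    d = total_norm - c
    p = fisher_one_sided_p(a, b, c, d)
    a_f = np.where(c == 0, a + 0.5, a).astype(float)
    c_f = np.where(c == 0, c + 0.5, c).astype(float)
    fold = (a_f / total_tissue) / (c_f / total_norm)
    return pd.DataFrame(
        {
            "motif": motifs,
            "tissue_id": tissue_table.tissue_id,
            "normalization_scheme": scheme,
            "count_tissue": a,
            "total_tissue": total_tissue,
            "count_norm": c,
            "total_norm": total_norm,
            "fold_change": fold,
            "p_value": p,
        }
    ).reset_index(drop=True)


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_and_flag(
    results: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    min_fold: float = DEFAULT_MIN_FOLD,
) -> pd.DataFrame:
    """Attach BH-adjusted p-values and the tissue-selectivity flag.

    The BH family is all motifs tested for one (tissue, scheme) pair.
    """
    out = results.copy()
    out["p_adjusted"] = np.nan
    for _, idx in out.groupby(["tissue_id", "normalization_scheme"]).groups.items():
        out.loc[idx, "p_adjusted"] = bh_adjust(out.loc[idx, "p_value"].to_numpy())
    out["selective"] = (out["p_adjusted"] < alpha) & (out["fold_change"] > min_fold)
    return out


def select_tissue_selective(
    results: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    min_fold: float = DEFAULT_MIN_FOLD,
) -> tuple[set[str], pd.DataFrame]:
    """Tissue-selective motif set plus the volcano table (log2 fold vs -log2 p).

    Accepts the output of :func:`adjust_and_flag`; if the adjusted column is
    missing it is computed first.
    """
    if "p_adjusted" not in results.columns:
        results = adjust_and_flag(results, alpha, min_fold)
    selective = (results["p_adjusted"] < alpha) & (results["fold_change"] > min_fold)
    volcano = pd.DataFrame(
        {
            "motif": results["motif"],
            "tissue_id": results["tissue_id"],
            "log2_fold_change": np.log2(np.clip(results["fold_change"], 1e-300, None)),
            "neg_log2_p_adjusted": -np.log2(np.clip(results["p_adjusted"], 1e-300, None)),
            "selective": selective,
        }
    )
    return set(results.loc[selective, "motif"]), volcano


def enrich_tissue(
    tissue_peptides: Iterable[PeptideRecord | str],
    norm_peptides: Iterable[PeptideRecord | str],
    scheme: str = "library",
    weighting: str = "unique_peptide",
    alpha: float = DEFAULT_ALPHA,
    min_fold: float = DEFAULT_MIN_FOLD,
    tissue_id: str = "tissue",
    k: int = 3,
) -> pd.DataFrame:
    """Convenience wrapper: count motifs in both samples, test, adjust, flag."""
    tissue_table = count_motifs(tissue_peptides, weighting, k, tissue_id=tissue_id)
    norm_table = count_motifs(norm_peptides, weighting, k, tissue_id=scheme)
    results = fisher_enrichment(tissue_table, norm_table, scheme)
    return adjust_and_flag(results, alpha=alpha, min_fold=min_fold)
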