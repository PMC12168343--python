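"""Spike-in-normalized expression quantification and gene-set enrichment.

RPKM = count / (exon length in kb) / (total mapped reads in millions).  To
compare samples with global abundance shifts, per-sample RPKMs are rescaled
so that the summed RPKM of exogenous constant-abundance spike-ins is equal
across samples (the reference level is the cross-sample mean of the spike-in
sums).  Differential labels are fold-change-based on adjusted RPKM; category
over-representation uses the hypergeometric upper tail with a minimum-overlap
prefilter and Bonferroni correction over the tested categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionTable",
    "EnrichmentParams",
    "rpkm",
    "spikein_normalize",
    "classify_de",
    "category_enrichment",
]

PSEUDO_RPKM = 0.01  # ratio floor; only matters near the detection filter


@dataclass
class ExpressionTable:
    """Raw counts plus derived (adjusted) RPKM for a set of samples.

    ``counts`` is features x samples; ``exon_length`` (bp) and the spike-in
    flag index the same features.  ``total_mapped`` defaults to the per-sample
    count sums.  ``rpkm``/``adjusted`` are filled by :func:`spikein_normalize`.
    """

    counts: pd.DataFrame
    exon_length: pd.Series
    spikein_ids: frozenset
    total_mapped: pd.Series | None = None
    rpkm: pd.DataFrame | None = None
    adjusted: pd.DataFrame | None = None
    scale_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be >= 0")
        self.exon_length = self.exon_length.reindex(self.counts.index)
        if self.exon_length.isna().any() or (self.exon_length <= 0).any():
            raise ValueError("every feature needs exon_length > 0")
        unknown = self.spikein_ids - set(self.counts.index)
        if unknown:
            raise ValueError(f"spike-in ids not in table: {sorted(unknown)[:3]}")
        if self.total_mapped is None:
            self.total_mapped = self.counts.sum(axis=0)
        if (self.total_mapped <= 0).any():
            raise ValueError("total mapped reads must be > 0 in every sample")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionTable":
        """Build from a simulate_expression-style table (exon_length and
        is_spikein columns alongside per-sample counts)."""
        meta = {"exon_length", "is_spikein"}
        samples = [c for c in frame.columns if c not in meta]
        return cls(
            counts=frame[samples].astype(float),
            exon_length=frame["exon_length"].astype(float),
            spikein_ids=frozenset(frame.index[frame["is_spikein"]]),
        )

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def rpkm(count, exon_length_bp, total_mapped):
    """Reads per kilobase of exon per million mapped reads."""
    exon_length_bp = np.asarray(exon_length_bp, dtype=float)
    total_mapped = np.asarray(total_mapped, dtype=float)
    if (exon_length_bp <= 0).any():
        raise ValueError("exon length must be > 0")
    if (total_mapped <= 0).any():
        raise ValueError("total mapped reads must be > 0")
    return np.asarray(count, dtype=float) / (exon_length_bp / 1e3) / (
        total_mapped / 1e6
    )


def spikein_normalize(table: ExpressionTable) -> ExpressionTable:
    """Fill ``rpkm`` and ``adjusted`` so spike-in RPKM sums match across samples.

    Per-sample factor = mean over samples of spike-in RPKM sums, divided by
    that sample's spike-in sum; adjusted RPKM = RPKM x factor.  The mean
    reference keeps adjusted values on the scale of raw RPKM.
    """
    if not table.spikein_ids:
        raise ValueError("no spike-in rows; cannot normalize")
    rk = pd.DataFrame(
        rpkm(
            table.counts.to_numpy(),
            table.exon_length.to_numpy()[:, None],
            table.total_mapped.to_numpy()[None, :],
        ),
        index=table.counts.index,
        columns=table.counts.columns,
    )
    spike_sums = rk.loc[sorted(table.spikein_ids)].sum(axis=0)
    if (spike_sums <= 0).any():
        bad = spike_sums.index[spike_sums <= 0].tolist()
        raise ValueError(f"zero spike-in RPKM sum in samples {bad}")
    factors = spike_sums.mean() / spike_sums
    table.rpkm = rk
    table.scale_factors = factors
    table.adjusted = rk * factors
    return table


def classify_de(
    table: ExpressionTable, fold_cutoff: float = 2.0, min_expr: float = 0.1
) -> pd.Series:
    """Label each gene up/down/unchanged/undetected from adjusted RPKM.

    Requires exactly two samples (condition 1, condition 2).  Genes below
    ``min_expr`` in both conditions are undetected; otherwise the
    condition2/condition1 ratio (with a small pseudo-RPKM floor) is compared
    to ``fold_cutoff``.  Spike-in rows are excluded.
    """
    if table.adjusted is None:
        raise ValueError("run spikein_normalize first")
    if fold_cutoff <= 1:
        raise ValueError("fold_cutoff must be > 1")
    if table.adjusted.shape[1] != 2:
        raise ValueError("classification needs exactly 2 conditions")
    adj = table.adjusted.drop(index=sorted(table.spikein_ids))
    a = adj.iloc[:, 0].to_numpy()
    b = adj.iloc[:, 1].to_numpy()
    ratio = np.maximum(b, PSEUDO_RPKM) / np.maximum(a, PSEUDO_RPKM)
    labels = np.where(
        (a < min_expr) & (b < min_expr),
        "undetected",
        np.where(
            ratio >= fold_cutoff,
            "up",
            np.where(ratio <= 1 / fold_cutoff, "down", "unchanged"),
        ),
    )
    return pd.Series(labels, index=adj.index, name="de_label")


@dataclass
class EnrichmentParams:
    """Significance filters for category over-representation."""

    min_genes: int = 10
    alpha_corrected: float = 0.01

    def __post_init__(self) -> None:
        if self.min_genes < 1:
            raise ValueError("min_genes must be >= 1")
        if not (0 < self.alpha_corrected < 1):
            raise ValueError("alpha_corrected must be in (0, 1)")


def category_enrichment(
    selected: Iterable[str],
    categories: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    params: EnrichmentParams | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` in each category.

    p_raw is the upper-tail P(overlap >= observed) for drawing |selected|
    genes from the universe.  Categories overlapping ``selected`` in fewer
    than ``min_genes`` genes are dropped before Bonferroni correction, so the
    correction denominator is the number of categories actually tested.
    """
    params = params or EnrichmentParams()
    universe = set(universe)
    selected = set(selected)
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    rows = []
    for cat, members in categories.items():
        members = set(members) & universe
        overlap = len(members & selected)
        if overlap < params.min_genes:
            continue
        p_raw = float(
            stats.hypergeom.sf(
                overlap - 1, len(universe), len(members), len(selected)
            )
        )
        rows.append((cat, len(members), overlap, p_raw))
    n_tested = len(rows)
    out = pd.DataFrame(
        rows, columns=["category", "category_size", "overlap", "p_raw"]
    )
    if n_tested:
        out["p_bonferroni"] = np.minimum(out["p_raw"] * n_tested, 1.0)
        out["significant"] = out["p_bonferroni"] < params.alpha_corrected
        out = out.sort_values("p_raw", kind="stable").reset_index(drop=True)
    else:
        out["p_bonferroni"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out
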