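"""Genomic-window enrichment of significant polymorphisms.

Given genome-wide SNPs flagged significant/non-significant, tests each
non-overlapping 1-Mb window for containing more significant SNPs than
expected from the chromosome-wide mix, with a hypergeometric upper tail:
the urn is all SNPs on the chromosome, successes are its significant
SNPs, and the draws are the SNPs falling in the window.  P-values are
pooled genome-wide and adjusted by Benjamini-Hochberg FDR.  The same
hypergeometric machinery serves over/under-representation tests of
annotation classes (e.g. enzyme classes) against a genome background.

Coordinates are 1-based; windows are anchored at position 1 with
inclusive ends, so position 1,000,000 is in window 1 and 1,000,001 in
window 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SnpRecord",
    "WindowResult",
    "window_enrichment",
    "bh_adjust",
    "class_representation",
    "windows_to_frame",
]

DEFAULT_WINDOW_SIZE = 1_000_000


@dataclass(frozen=True)
class SnpRecord:
    chrom: str
    pos: int
    significant: bool

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if self.pos < 1:
            raise ValueError("positions are 1-based (pos >= 1)")


@dataclass
class WindowResult:
    chrom: str
    window_start: int   # 1-based inclusive
    window_end: int     # inclusive
    n_total: int
    n_sig: int
    p_upper: float
    q_bh: float = float("nan")


def window_enrichment(
    snps: Sequence[SnpRecord],
    window_size: int = DEFAULT_WINDOW_SIZE,
    adjust: bool = True,
) -> list[WindowResult]:
    """Hypergeometric upper-tail enrichment per non-overlapping window.

    For a window holding n SNPs of which k are significant, on a
    chromosome with N SNPs of which K are significant,
    p = P(X >= k) for X ~ Hypergeometric(N, K, n).  Windows without SNPs
    are skipped.  With ``adjust`` the BH-FDR q-values are filled, pooled
    across all windows genome-wide.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    df = pd.DataFrame(
        {
            "chrom": [s.chrom for s in snps],
            "pos": [s.pos for s in snps],
            "sig": [bool(s.significant) for s in snps],
        }
    )
    if df.empty:
        raise ValueError("no SNPs supplied")
    df["window"] = (df["pos"] - 1) // window_size
    results: list[WindowResult] = []
    for chrom, sub in df.groupby("chrom", sort=True):
        N = len(sub)
        K = int(sub["sig"].sum())
        for w, wsub in sub.groupby("window", sort=True):
            n = len(wsub)
            k = int(wsub["sig"].sum())
            p = float(hypergeom.sf(k - 1, N, K, n))
            p = min(p, 1.0)
            results.append(
                WindowResult(
                    chrom=str(chrom),
                    window_start=int(w) * window_size + 1,
                    window_end=(int(w) + 1) * window_size,
                    n_total=n,
                    n_sig=k,
                    p_upper=p,
                )
            )
    if adjust and results:
        qs = bh_adjust([r.p_upper for r in results])
        for r, q in zip(results, qs):
            r.q_bh = q
    return results


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order kept."""
    ps = list(pvals)
    if not ps:
        return []
    if any(not (0.0 < p <= 1.0) for p in ps):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(ps, method="fdr_bh")
    return [float(v) for v in q]


def class_representation(
    k_in_list: int,
    n_list: int,
    K_genome: int,
    N_genome: int,
    direction: str = "over",
) -> float:
    """Over/under-representation of an annotation class in a gene list.

    With a genome of N genes, K of them in the class, and a list of n
    genes containing k class members: over -> P(X >= k); under ->
    P(X <= k) for X ~ Hypergeometric(N, K, n).
    """
    if direction not in ("over", "under"):
        raise ValueError("direction must be 'over' or 'under'")
    if not (0 <= k_in_list <= n_list <= N_genome and 0 <= K_genome <= N_genome):
        raise ValueError("inconsistent counts")
    if k_in_list > K_genome:
        raise ValueError("more class members in list than in genome")
    if direction == "over":
        p = hypergeom.sf(k_in_list - 1, N_genome, K_genome, n_list)
    else:
        p = hypergeom.cdf(k_in_list, N_genome, K_genome, n_list)
    return float(min(p, 1.0))


def windows_to_frame(results: Sequence[WindowResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in results],
            "start": [r.window_start for r in results],
            "end": [r.window_end for r in results],
            "n_total": [r.n_total for r in results],
            "n_sig": [r.n_sig for r in results],
            "p": [r.p_upper for r in results],
            "q": [r.q_bh for r in results],
        }
    )
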