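"""Promoter-proximal RNA polymerase II pausing index.

The pausing index of a gene is the ratio of initiating-polymerase
(RNAPII-S5P) signal density in a window around the TSS to the density
over the downstream gene body.  Engaged-but-paused polymerase piles up
near the promoter, so a higher index means more pausing.  Windows are
strand-aware: on the minus strand the gene body extends in decreasing
coordinates.  Mean density (not summed signal) is used in both windows
so the unequal window lengths compare as enrichment, and the index is
invariant to any global rescaling of the track.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic import GeneRecord, SignalTrack
from .stats import rank_sum_test

__all__ = ["PausingRecord", "pausing_index", "compare_pausing"]

PROXIMAL = 300
BODY_END = 5000


@dataclass
class PausingRecord:
    gene: str
    promoter_signal: float
    body_signal: float
    pi: float | None
    flag: str = ""


def pausing_index(
    track: SignalTrack,
    genes: list[GeneRecord],
    prox: int = PROXIMAL,
    body_end: int = BODY_END,
) -> list[PausingRecord]:
    """Pausing index per gene from a normalized S5P track.

    Promoter window: TSS ± ``prox``.  Body window: ``prox`` to
    ``body_end`` bp downstream of the TSS in the direction of
    transcription.  Means are length-weighted over track bins.  Genes
    whose body is shorter than ``body_end`` are flagged ``short_gene``
    and their body window truncated at the gene end; a zero body signal
    yields a missing index with reason ``zero_body``.
    """
    records = []
    for g in genes:
        if g.chrom not in track.data:
            records.append(PausingRecord(g.gene_id, np.nan, np.nan, None, "no_track"))
            continue
        eff_body = min(body_end, g.length)
        flag = "short_gene" if g.length < body_end else ""
        if g.strand == "+":
            prom_lo, prom_hi = g.tss - prox, g.tss + prox
            body_lo, body_hi = g.tss + prox, g.tss + eff_body
        else:
            prom_lo, prom_hi = g.tss - prox, g.tss + prox
            body_lo, body_hi = g.tss - eff_body, g.tss - prox
        if body_hi <= body_lo:
            records.append(
                PausingRecord(g.gene_id, np.nan, np.nan, None, "body_within_promoter")
            )
            continue
        prom = track.window_mean(g.chrom, prom_lo, prom_hi)
        body = track.window_mean(g.chrom, body_lo, body_hi)
        if not np.isfinite(body) or body == 0:
            records.append(PausingRecord(g.gene_id, prom, body, None, flag or "zero_body"))
        else:
            records.append(PausingRecord(g.gene_id, prom, body, prom / body, flag))
    short = sum(r.flag == "short_gene" for r in records)
    if short:
        warnings.warn(f"{short} genes shorter than body window; truncated and flagged")
    return records


def records_frame(records: list[PausingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "promoter_signal": [r.promoter_signal for r in records],
            "body_signal": [r.body_signal for r in records],
            "pi": [r.pi if r.pi is not None else np.nan for r in records],
            "flag": [r.flag for r in records],
        }
    )


def compare_pausing(
    wt: list[PausingRecord],
    kd: list[PausingRecord],
    gene_sets: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Per gene set: two-sided Mann-Whitney of WT vs KD pausing indices.

    Returns one row per set with the U statistic, p-value, the
    median(kd)/median(wt) ratio and the number of scored genes per
    condition.  Sets with fewer than 3 scored genes in either condition
    are skipped with a warning.  ``gene_sets=None`` compares all genes
    as one set named "all".
    """
    wt_pi = {r.gene: r.pi for r in wt if r.pi is not None}
    kd_pi = {r.gene: r.pi for r in kd if r.pi is not None}
    if gene_sets is None:
        gene_sets = {"all": sorted(set(wt_pi) | set(kd_pi))}
    rows = []
    for name, members in gene_sets.items():
        w = np.array([wt_pi[g] for g in members if g in wt_pi])
        k = np.array([kd_pi[g] for g in members if g in kd_pi])
        if len(w) < 3 or len(k) < 3:
            warnings.warn(f"gene set {name!r} has <3 scored genes; skipped")
            continue
        u, p = rank_sum_test(w, k)
        rows.append((name, u, p, float(np.median(k) / np.median(w)), len(w), len(k)))
    return pd.DataFrame(
        rows, columns=["set", "U", "p", "median_ratio", "n_wt", "n_kd"]
    )
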