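"""Spike-in / H3-control normalization of chromatin-mark libraries.

Each CUT&Tag (or ATAC) library is sequenced together with a fixed amount
of lambda-phage spike-in DNA, so the number of lambda reads measures the
effective sequencing depth of the library independently of how much
chromatin went in.  Rescaling a library by a factor inversely
proportional to its lambda count therefore removes depth differences.
Differences in starting material (nuclei) are removed with a second
factor derived from a total-H3 control library prepared from the same
nuclei pool: after spike normalization, the H3 library's genome read
count is proportional to the number of nuclei, so the ratio of a
reference H3 level to the sample's H3 level corrects the mark library to
per-nucleus scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .genomic import PeakSet, SignalTrack

__all__ = [
    "MarkLibrary",
    "SPIKE_SCALE",
    "spike_factor",
    "h3_correction",
    "normalized_track",
    "quantify_peaks",
    "subtract_exclusion",
]

STAGES = ("preC9", "C10_12", "C14")
MARKS = (
    "H3K27me3",
    "H3K27ac",
    "H3",
    "CBP",
    "Zelda",
    "GAF",
    "S5P",
    "S2P",
    "BRD4",
    "ATAC",
)

#: common scale constant K: a library with K lambda reads gets factor 1
SPIKE_SCALE = 1_000_000


@dataclass
class MarkLibrary:
    """One sequencing library for one (stage, mark, condition)."""

    sample_id: str
    stage: str
    mark: str
    condition: str
    raw_track: SignalTrack
    n_genome_reads: int
    n_lambda_reads: int
    paired_h3_sample: str | None = None

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.mark not in MARKS:
            raise ValueError(f"unknown mark {self.mark!r}")
        if self.n_genome_reads < 0 or self.n_lambda_reads < 0:
            raise ValueError("read counts must be non-negative")


def spike_factor(lib: MarkLibrary) -> float:
    """Depth-normalization factor ``K / n_lambda_reads``.

    Because every library receives the same amount of spike-in DNA, the
    lambda read count is proportional to sequencing depth; dividing it
    out puts libraries with equal spike-in content on a common scale.
    """
    if lib.n_lambda_reads < 1:
        raise ValueError(
            f"{lib.sample_id}: no lambda spike-in reads; spike normalization "
            "is undefined — process this library in unnormalized mode"
        )
    return SPIKE_SCALE / lib.n_lambda_reads


def h3_correction(lib: MarkLibrary, h3: MarkLibrary, h3_reference: MarkLibrary | None = None) -> float:
    """Starting-material correction from a paired total-H3 control.

    ``h3`` must be the H3 library from the same nuclei pool as ``lib``.
    The spike-normalized H3 genome read count is proportional to the
    number of nuclei in the pool; the correction rescales ``lib`` so its
    effective nuclei input matches that of ``h3_reference`` (defaults to
    ``h3`` itself, giving 1).
    """
    if h3.mark != "H3":
        raise ValueError(f"control library {h3.sample_id} is not an H3 library")
    if lib.paired_h3_sample is not None and lib.paired_h3_sample != h3.sample_id:
        raise ValueError(
            f"{lib.sample_id} is paired with H3 sample {lib.paired_h3_sample}, "
            f"got {h3.sample_id}"
        )
    if lib.paired_h3_sample is None:
        raise ValueError(f"{lib.sample_id} has no paired H3 sample")
    ref = h3_reference if h3_reference is not None else h3
    if ref.mark != "H3":
        raise ValueError("reference library must be an H3 library")
    if ref.n_genome_reads == 0 or h3.n_genome_reads == 0:
        raise ValueError("H3 library with zero genome reads cannot anchor the correction")
    ref_level = spike_factor(ref) * ref.n_genome_reads
    own_level = spike_factor(h3) * h3.n_genome_reads
    return ref_level / own_level


def normalized_track(
    lib: MarkLibrary,
    h3: MarkLibrary | None = None,
    h3_reference: MarkLibrary | None = None,
) -> SignalTrack:
    """Spike-normalized (and, when an H3 control is given, per-nucleus
    corrected) signal track."""
    factor = spike_factor(lib)
    if h3 is not None:
        factor *= h3_correction(lib, h3, h3_reference)
    return lib.raw_track.scaled(factor)


def quantify_peaks(
    track: SignalTrack, peaks: PeakSet, flank: int = 1000
) -> pd.Series:
    """Integrate normalized signal in a window around each peak center.

    For every peak the signal (value × bp) is summed over
    ``[center - flank, center + flank)`` where ``center`` is the peak
    midpoint; windows are truncated at chromosome ends.  Peaks on
    chromosomes absent from the track score 0 with a warning.
    """
    values = {}
    missing = []
    for iv in peaks:
        if iv.chrom not in track.data:
            missing.append(iv.id)
            values[iv.id] = 0.0
            continue
        c = iv.center
        values[iv.id] = track.window_sum(iv.chrom, c - flank, c + flank)
    if missing:
        warnings.warn(
            f"{len(missing)} peaks on chromosomes absent from track "
            f"(e.g. {missing[0]}); scored 0"
        )
    return pd.Series(values, name="signal")


def subtract_exclusion(peaks: PeakSet, exclusion: PeakSet) -> PeakSet:
    """Drop peaks overlapping any exclusion interval.

    Used to remove regions confounded by antibody cross-reaction (e.g.
    H3K9me3 intervals from an H3K27me3 peak set) before classification.
    """
    excl = exclusion.by_chrom()
    kept = []
    for iv in peaks:
        hits = excl.get(iv.chrom, ())
        if not any(iv.start < e.end and e.start < iv.end for e in hits):
            kept.append(iv)
    return PeakSet(kept)
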