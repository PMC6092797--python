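"""Positional motif enrichment, windowed tetramer tests, conservation profiles.

Motif classes (DNA alphabet, T for U):

- ``YCAY``: the NOVA recognition element, Y = C or T;
- ``YYYY``: polypyrimidine tetramers;
- ``U-rich``: tetramers with two or more T.

Positional profiles report, per offset relative to peak centers (strand
oriented), the fraction of peaks with a class-matching 4-mer starting
there, normalised by the expectation under the i.i.d. mononucleotide
composition of the analysed sequence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .models import Genome
from .statcore import bh_fdr, hypergeom_upper_tail

MOTIF_CLASSES = ("YCAY", "YYYY", "U-rich")
_PYRIMIDINES = frozenset("CT")


def matches_motif_class(tetramer: str, motif_class: str) -> bool:
    if len(tetramer) != 4:
        raise ValueError("tetramer expected")
    if motif_class == "YCAY":
        return (
            tetramer[0] in _PYRIMIDINES
            and tetramer[1] == "C"
            and tetramer[2] == "A"
            and tetramer[3] in _PYRIMIDINES
        )
    if motif_class == "YYYY":
        return all(b in _PYRIMIDINES for b in tetramer)
    if motif_class == "U-rich":
        return tetramer.count("T") >= 2
    raise ValueError(f"unknown motif class {motif_class!r}")


def expected_motif_probability(composition: dict[str, float], motif_class: str) -> float:
    """Probability that an i.i.d. 4-mer matches the class."""
    p = composition
    e = 0.0
    for tet in map("".join, product("ACGT", repeat=4)):
        if matches_motif_class(tet, motif_class):
            e += p[tet[0]] * p[tet[1]] * p[tet[2]] * p[tet[3]]
    if e == 0.0:
        raise ValueError(f"degenerate composition: expected {motif_class} frequency is 0")
    return e


@dataclass
class MotifProfile:
    motif_class: str
    offsets: np.ndarray
    observed_freq: np.ndarray
    expected_freq: float
    enrichment: np.ndarray
    n_peaks: int
    n_dropped: int


def _peak_window_seq(peak, genome: Genome, half_window: int) -> str | None:
    """Strand-oriented sequence covering 4-mer starts at every offset."""
    center = peak.center
    if peak.strand == "+":
        lo, hi = center - half_window, center + half_window + 4
    else:
        lo, hi = center - half_window - 3, center + half_window + 1
    if lo < 0 or hi > genome.length(peak.chrom):
        return None
    return genome.fetch(peak.chrom, lo, hi, peak.strand)


def positional_motif_enrichment(
    peaks,
    genome: Genome,
    motif_class: str,
    half_window: int = 500,
    composition: dict[str, float] | None = None,
) -> MotifProfile:
    """Observed/expected motif-start frequency per offset around peak centers.

    Peaks whose window leaves the chromosome are dropped and counted.
    ``composition`` defaults to the whole-genome mononucleotide composition.
    """
    comp = composition or genome.composition()
    expected = expected_motif_probability(comp, motif_class)
    width = 2 * half_window + 1
    hits = np.zeros(width)
    n_used = n_dropped = 0
    for peak in peaks:
        seq = _peak_window_seq(peak, genome, half_window)
        if seq is None:
            n_dropped += 1
            continue
        n_used += 1
        for x in range(width):
            if matches_motif_class(seq[x : x + 4], motif_class):
                hits[x] += 1
    if n_used == 0:
        raise ValueError("no peaks with full windows")
    observed = hits / n_used
    return MotifProfile(
        motif_class=motif_class,
        offsets=np.arange(-half_window, half_window + 1),
        observed_freq=observed,
        expected_freq=expected,
        enrichment=observed / expected,
        n_peaks=n_used,
        n_dropped=n_dropped,
    )


def profile_to_frame(profile: MotifProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "offset": profile.offsets,
            "observed": profile.observed_freq,
            "expected": profile.expected_freq,
            "enrichment": profile.enrichment,
            "n": profile.n_peaks,
        }
    )


def _window_tetramer_counts(peaks, genome: Genome, half_window: int):
    counts: Counter[str] = Counter()
    total = 0
    for peak in peaks:
        seq = _peak_window_seq(peak, genome, half_window)
        if seq is None:
            continue
        for x in range(len(seq) - 3):
            tet = seq[x : x + 4]
            if "N" not in tet:
                counts[tet] += 1
                total += 1
    return counts, total


def tetramer_window_enrichment(
    target_peaks, background_peaks, genome: Genome, half_window: int = 100
) -> pd.DataFrame:
    """Hypergeometric enrichment of each tetramer in target vs background windows.

    Tetramer occurrences ``half_window`` nt around each peak center are
    counted; the upper-tail hypergeometric p treats target occurrences as
    draws from the pooled background occurrences. Overlapping windows
    double-count by design. BH across all 256 tetramers.
    """
    if not target_peaks:
        raise ValueError("empty target peak set")
    count_t, total_t = _window_tetramer_counts(target_peaks, genome, half_window)
    count_b, total_b = _window_tetramer_counts(background_peaks, genome, half_window)
    rows = []
    for tet in map("".join, product("ACGT", repeat=4)):
        ct, cb = count_t.get(tet, 0), count_b.get(tet, 0)
        p = (
            1.0
            if cb == 0
            else hypergeom_upper_tail(total_b, cb, total_t, min(ct, cb, total_t))
        )
        rows.append({"tetramer": tet, "count_target": ct, "count_background": cb, "p_value": p})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p_value"])
    return out.sort_values(["fdr", "p_value", "tetramer"], kind="mergesort").reset_index(drop=True)


@dataclass
class ConservationProfile:
    offsets: np.ndarray
    mean_score: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray
    n: np.ndarray


def conservation_profile(
    peaks, track: dict[str, np.ndarray], half_window: int = 100
) -> ConservationProfile:
    """Per-offset mean conservation score around peak centers, with normal
    95% CIs. Bases missing from the track are absent (NaN), not zero;
    offsets with n < 2 get no CI."""
    width = 2 * half_window + 1
    rows = []
    for peak in peaks:
        arr = track[peak.chrom]
        lo, hi = peak.center - half_window, peak.center + half_window + 1
        if lo < 0 or hi > len(arr):
            continue
        window = arr[lo:hi]
        rows.append(window[::-1] if peak.strand == "-" else window)
    if not rows:
        raise ValueError("no peaks with full windows")
    mat = np.vstack(rows)
    n = np.sum(~np.isnan(mat), axis=0)
    import warnings

    with warnings.catch_warnings():
        # offsets with no covered base legitimately average to NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(mat, axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1)
    half = np.where(n >= 2, 1.96 * sd / np.sqrt(np.maximum(n, 1)), np.nan)
    mean = np.where(n == 0, np.nan, mean)
    return ConservationProfile(
        offsets=np.arange(-half_window, half_window + 1),
        mean_score=mean,
        ci95_low=mean - half,
        ci95_high=mean + half,
        n=n,
    )
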