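"""Peak/valley classification of motif conservation profiles.

A motif's per-position information content is segmented into HIGH
(conserved) and LOW (unconserved) runs.  An interior HIGH run flanked by
LOW on both sides is a *peak*; an interior LOW run flanked by HIGH on
both sides is a *valley*.  The arrangement of peaks and valleys sorts
motifs into seven archetypes — single/double/triple peak, single/
double/triple valley, quadruple peak — reflecting how a dimeric
regulator's recognition helices contact the operator; profiles that fit
none of these are labelled OTHER.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ConservationProfile

DEFAULT_HIGH_THRESH = 1.0  # bits
DEFAULT_LOW_THRESH = 0.5  # bits
DEFAULT_MIN_RUN = 2


class MotifType(enum.Enum):
    TYPE_1 = "single peak"
    TYPE_2 = "single valley"
    TYPE_3 = "double peak"
    TYPE_4 = "double valley"
    TYPE_5 = "triple peak"
    TYPE_6 = "triple valley"
    TYPE_7 = "quadruple peak"
    OTHER = "unclassifiable"

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class Run:
    label: str  # "HIGH" or "LOW"
    start: int
    length: int


@dataclass(frozen=True)
class SegmentLabeling:
    """HIGH/LOW runs tiling a conservation profile."""

    runs: tuple[Run, ...]
    thresholds: tuple[float, float]  # (high, low)

    def __post_init__(self):
        pos = 0
        for i, r in enumerate(self.runs):
            if r.start != pos or r.length < 1:
                raise ValueError("runs must tile the profile without gaps")
            if i and r.label == self.runs[i - 1].label:
                raise ValueError("adjacent runs must have different labels")
            pos += r.length

    @property
    def width(self) -> int:
        return sum(r.length for r in self.runs)


def _labels_to_runs(labels: list[str]) -> list[Run]:
    runs: list[Run] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append(Run(labels[start], start, i - start))
            start = i
    return runs


def label_segments(
    profile: ConservationProfile,
    high_thresh: float = DEFAULT_HIGH_THRESH,
    low_thresh: float = DEFAULT_LOW_THRESH,
    min_run: int = DEFAULT_MIN_RUN,
) -> SegmentLabeling:
    """Segment a profile into alternating HIGH/LOW runs.

    Positions at or above ``high_thresh`` are HIGH, at or below
    ``low_thresh`` are LOW.  Intermediate positions join the neighbouring
    run whose threshold their value is closer to (or the only available
    neighbour at profile edges).  Runs shorter than ``min_run`` are then
    merged into their longer neighbour until all runs are long enough.
    """
    if not low_thresh < high_thresh:
        raise ValueError("need low_thresh < high_thresh")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    v = profile.values
    w = v.size
    raw = ["HIGH" if x >= high_thresh else "LOW" if x <= low_thresh else "MID" for x in v]
    # resolve intermediate positions
    labels = list(raw)
    i = 0
    while i < w:
        if labels[i] != "MID":
            i += 1
            continue
        j = i
        while j < w and labels[j] == "MID":
            j += 1
        left = labels[i - 1] if i > 0 else None
        right = labels[j] if j < w else None
        for t in range(i, j):
            if left is not None and right is not None and left != right:
                choice = "HIGH" if abs(v[t] - high_thresh) <= abs(v[t] - low_thresh) else "LOW"
            elif left is not None:
                choice = left
            elif right is not None:
                choice = right
            else:  # whole profile intermediate
                choice = "HIGH" if abs(v[t] - high_thresh) <= abs(v[t] - low_thresh) else "LOW"
            labels[t] = choice
        i = j
    runs = _labels_to_runs(labels)
    # absorb short runs into the longer neighbour
    while len(runs) > 1:
        short = [
            (r.length, idx) for idx, r in enumerate(runs) if r.length < min_run
        ]
        if not short:
            break
        _, idx = min(short)
        if idx == 0:
            target = 1
        elif idx == len(runs) - 1:
            target = idx - 1
        else:
            target = idx - 1 if runs[idx - 1].length >= runs[idx + 1].length else idx + 1
        merged_label = runs[target].label
        labels[runs[idx].start: runs[idx].start + runs[idx].length] = (
            [merged_label] * runs[idx].length
        )
        runs = _labels_to_runs(labels)
    return SegmentLabeling(runs=tuple(runs), thresholds=(high_thresh, low_thresh))


def count_peaks_valleys(labeling: SegmentLabeling) -> tuple[int, int]:
    """Interior HIGH runs flanked by LOW (peaks) and vice versa (valleys)."""
    runs = labeling.runs
    peaks = valleys = 0
    for i in range(1, len(runs) - 1):
        if runs[i].label == "HIGH":
            peaks += 1
        else:
            valleys += 1
    return peaks, valleys


def classify_type(labeling: SegmentLabeling) -> MotifType:
    """Map a peak/valley arrangement to one of the seven archetypes.

    Multi-feature profiles are resolved from most features down (four
    peaks before three, etc.), since e.g. a double-peak profile
    necessarily contains one interior valley; profiles matching no
    archetype (including mixed single-peak-plus-valley shapes) are OTHER.
    """
    k, nv = count_peaks_valleys(labeling)
    if k == 4:
        return MotifType.TYPE_7
    if k == 3:
        return MotifType.TYPE_5
    if nv == 3:
        return MotifType.TYPE_6
    if k == 2:
        return MotifType.TYPE_3
    if nv == 2:
        return MotifType.TYPE_4
    if k == 1 and nv == 0:
        return MotifType.TYPE_1
    if nv == 1 and k == 0:
        return MotifType.TYPE_2
    return MotifType.OTHER


def classify_profile(
    profile: ConservationProfile,
    high_thresh: float = DEFAULT_HIGH_THRESH,
    low_thresh: float = DEFAULT_LOW_THRESH,
    min_run: int = DEFAULT_MIN_RUN,
) -> MotifType:
    """Convenience: segment then classify in one call."""
    return classify_type(label_segments(profile, high_thresh, low_thresh, min_run))


def type_census(clusters) -> pd.DataFrame:
    """Tabulate motif types over typed clusters: (type, count, fraction)."""
    types = [c.motif_type for c in clusters]
    if any(t is None for t in types):
        raise ValueError("all clusters must be typed before the census")
    if not types:
        return pd.DataFrame(columns=["type", "count", "fraction"])
    counts: dict[MotifType, int] = {}
    for t in types:
        counts[t] = counts.get(t, 0) + 1
    rows = [
        {"type": t.name, "count": c, "fraction": c / len(types)}
        for t, c in sorted(counts.items(), key=lambda kv: kv[0].name)
    ]
    return pd.DataFrame(rows)


def plot_ic_profile(profile: ConservationProfile, path, title: str = "") -> None:
    """Bar plot of per-position information content (bits)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, profile.width / 3), 2.5))
    ax.bar(np.arange(profile.width), profile.values, color="#4477aa")
    ax.set_ylim(0, 2)
    ax.set_xlabel("position")
    ax.set_ylabel("information (bits)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
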