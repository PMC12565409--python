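"""Synthetic promoter sets and motif atlases with planted ground truth.

Emulates the input a regulator-family pipeline sees: sets of ~200 bp
upstream regions, a fraction of which carry a site sampled from a
palindromic truth PWM whose conservation profile realises a chosen
peak/valley archetype (conserved half-sites separated by a weakly
conserved 12-14 bp spacer in the classic single-valley layout).  Every
output is a deterministic function of the seed, and the planted truth
(PWM plus site coordinates) is returned alongside, so discovery,
scanning, clustering and typing can all be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .conservation import MotifType
from .matrix import (
    BASES,
    COMPLEMENT_ROWS,
    FrequencyMatrix,
    MotifRecord,
)
from .sequence_io import UpstreamSet

#: HIGH/LOW block layout realising each archetype (symmetric, odd count).
_TYPE_PATTERNS = {
    MotifType.TYPE_1: "LHL",
    MotifType.TYPE_2: "HLH",
    MotifType.TYPE_3: "LHLHL",
    MotifType.TYPE_4: "HLHLH",
    MotifType.TYPE_5: "LHLHLHL",
    MotifType.TYPE_6: "HLHLHLH",
    MotifType.TYPE_7: "LHLHLHLHL",
}


class LayoutError(ValueError):
    """The requested archetype does not fit in the requested width."""


@dataclass(frozen=True)
class PlantConfig:
    """What to plant and where.

    ``high_ic``/``low_ic`` set the information content (bits) of
    conserved and unconserved blocks.  ``spacer`` is the centre-to-
    centre separation of the palindrome's two half-sites (12-14 bp in
    dimeric HTH operators, matching the spacing of adjacent major
    grooves); it shapes the classic half-site/gap/half-site layout and
    is ignored for archetypes it cannot apply to.
    """

    motif_type: MotifType = MotifType.TYPE_2
    width: int = 17
    spacer: int = 13
    high_ic: float = 2.0
    low_ic: float = 0.15
    n_sequences: int = 200
    seq_length: int = 200
    plant_frequency: float = 0.8
    gc_content: float = 0.5
    seed: int = 0
    min_block: int = 2
    random_strand: bool = False

    def __post_init__(self):
        if self.motif_type not in _TYPE_PATTERNS:
            raise ValueError(f"cannot plant motif type {self.motif_type}")
        if self.width < self.spacer + 2:
            raise ValueError("width must be >= spacer + 2")
        if not 0.0 <= self.plant_frequency <= 1.0:
            raise ValueError("plant_frequency must lie in [0, 1]")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie in (0, 1)")
        if not 0.0 <= self.low_ic < self.high_ic <= 2.0:
            raise ValueError("need 0 <= low_ic < high_ic <= 2")
        if self.seq_length < self.width:
            raise ValueError("seq_length must be >= width")


@dataclass(frozen=True)
class PlantTruth:
    """Ground truth: the planted PWM and every (sequence index, start, strand)."""

    truth_pwm: FrequencyMatrix
    plants: tuple[tuple[int, int, str], ...]


def _dominant_prob_for_ic(ic: float) -> float:
    """Probability of the dominant base in a single-dominant column with
    the requested information content (remaining mass split 3 ways)."""
    def f(p):
        q = (1.0 - p) / 3.0
        ent = -(p * np.log2(p) + (3 * q * np.log2(q) if q > 0 else 0.0))
        return 2.0 - ent - ic

    if ic <= 1e-9:
        return 0.25
    if ic >= 2.0 - 1e-9:
        return 1.0
    return float(brentq(f, 0.25 + 1e-12, 1.0 - 1e-12))


def _pair_prob_for_ic(ic: float) -> float:
    """Probability r of each of the two complementary bases in a
    self-complementary column (r, s, s, r); IC capped at 1 bit."""
    ic = min(ic, 1.0)

    def f(r):
        s = 0.5 - r
        ent = -2.0 * (r * np.log2(r) + (s * np.log2(s) if s > 0 else 0.0))
        return 2.0 - ent - ic

    if ic >= 1.0 - 1e-9:
        return 0.5
    return float(brentq(f, 0.25 + 1e-12, 0.5 - 1e-12))


def _block_sizes(config: PlantConfig) -> list[int]:
    """Symmetric block widths for the archetype's HIGH/LOW pattern."""
    pattern = _TYPE_PATTERNS[config.motif_type]
    nb = len(pattern)
    w, mb = config.width, config.min_block
    if nb * mb > w:
        raise LayoutError(
            f"{config.motif_type.name} needs >= {nb * mb} columns at "
            f"min_block={mb}, width {w} is too narrow"
        )
    center = nb // 2
    # classic palindrome: honour the spacer as the centre-to-centre
    # separation of the two half-sites (half width h = W - spacer,
    # unconserved gap = 2*spacer - W)
    if pattern == "HLH":
        h = w - config.spacer
        gap = 2 * config.spacer - w
        if h >= mb and gap >= mb:
            return [h, gap, h]
    sizes = [mb] * nb
    extra = w - nb * mb
    sizes[center] += extra % 2
    extra -= extra % 2
    i = 0
    pairs = nb // 2
    while extra > 0:
        if pairs == 0:
            sizes[center] += extra
            break
        p = i % pairs
        sizes[p] += 1
        sizes[nb - 1 - p] += 1
        extra -= 2
        i += 1
    return sizes


def build_truth_pwm(config: PlantConfig) -> FrequencyMatrix:
    """A palindromic PWM whose IC profile realises the requested archetype.

    Conserved blocks carry one dominant base per column at ``high_ic``
    bits, unconserved blocks a weak preference at ``low_ic`` bits;
    dominant bases are drawn at random (seeded) with the complement
    mirrored across the centre so the matrix equals its own reverse
    complement.  An odd-width conserved centre column uses a
    self-complementary A/T or C/G pair (IC capped at 1 bit, the maximum
    such a column allows).
    """
    sizes = _block_sizes(config)
    pattern = _TYPE_PATTERNS[config.motif_type]
    w = config.width
    col_ic = np.empty(w)
    pos = 0
    for label, size in zip(pattern, sizes):
        col_ic[pos:pos + size] = config.high_ic if label == "H" else config.low_ic
        pos += size
    rng = np.random.default_rng(config.seed)
    probs = np.empty((4, w))
    for j in range(w // 2):
        p = _dominant_prob_for_ic(col_ic[j])
        q = (1.0 - p) / 3.0
        base = int(rng.integers(4))
        col = np.full(4, q)
        col[base] = p
        probs[:, j] = col
        probs[:, w - 1 - j] = col[COMPLEMENT_ROWS]
    if w % 2 == 1:
        c = w // 2
        r = _pair_prob_for_ic(col_ic[c])
        s = 0.5 - r
        if rng.integers(2) == 0:
            probs[:, c] = [r, s, s, r]  # A/T pair
        else:
            probs[:, c] = [s, r, r, s]  # C/G pair
    return FrequencyMatrix(probs=probs)


def generate_upstream_set(config: PlantConfig) -> tuple[UpstreamSet, PlantTruth]:
    """Background sequences with sites planted from the truth PWM.

    iid background at the configured GC content; a site sampled
    column-wise from the truth PWM is planted at a uniform random
    position in ``round(plant_frequency * n_sequences)`` sequences (one
    site per chosen sequence, forward strand unless ``random_strand``).
    Fully deterministic under the seed.
    """
    truth = build_truth_pwm(config)
    rng = np.random.default_rng([config.seed, 9151])
    n, length, w = config.n_sequences, config.seq_length, config.width
    gc = config.gc_content
    bg = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seqs = rng.choice(4, size=(n, length), p=bg)
    n_plant = int(round(config.plant_frequency * n))
    chosen = np.sort(rng.choice(n, size=n_plant, replace=False))
    plants: list[tuple[int, int, str]] = []
    base_arr = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    for si in chosen:
        site = np.array(
            [rng.choice(4, p=truth.probs[:, j]) for j in range(w)], dtype=np.int64
        )
        strand = "+"
        if config.random_strand and rng.integers(2) == 1:
            strand = "-"
            site = site[::-1]
            site = np.array([3, 2, 1, 0])[site]
        start = int(rng.integers(0, length - w + 1))
        seqs[si, start:start + w] = site
        plants.append((int(si), start, strand))
    ndigits = max(4, len(str(n)))
    pairs = [
        (f"seq_{i:0{ndigits}d}", base_arr[seqs[i]].tobytes().decode())
        for i in range(n)
    ]
    upstream = UpstreamSet.from_sequences(pairs, name=f"synthetic_seed{config.seed}")
    return upstream, PlantTruth(truth_pwm=truth, plants=tuple(plants))


def write_truth(truth: PlantTruth, upstream: UpstreamSet, tsv_path) -> None:
    """Plant coordinates as a TSV (sequence_id, start, strand; 0-based)."""
    with open(tsv_path, "w") as fh:
        fh.write("# 0-based plant start positions\n")
        fh.write("sequence_id\tstart\tstrand\n")
        for si, start, strand in truth.plants:
            fh.write(f"{upstream[si].gene_id}\t{start}\t{strand}\n")


def generate_atlas(
    family_configs: list[PlantConfig],
    motifs_per_family: int = 6,
    jitter_concentration: float = 200.0,
    nsites: int = 60,
    seed: int = 0,
) -> tuple[list[MotifRecord], list[int]]:
    """Noisy motif copies from several planted families, with truth labels.

    Each family's truth PWM is replicated ``motifs_per_family`` times
    with per-column Dirichlet jitter (concentration
    ``jitter_concentration * p + 0.1``; larger = tighter copies;
    ``inf`` or <= 0 disables jitter).  Returns the motif records plus the
    family index of each, for adjusted-Rand scoring of clustering.
    """
    if len(family_configs) < 2:
        raise ValueError("an atlas needs at least 2 families")
    rng = np.random.default_rng([seed, 40427])
    motifs: list[MotifRecord] = []
    labels: list[int] = []
    for fi, cfg in enumerate(family_configs):
        truth = build_truth_pwm(cfg)
        for mi in range(motifs_per_family):
            if jitter_concentration and np.isfinite(jitter_concentration) \
                    and jitter_concentration > 0:
                probs = np.empty_like(truth.probs)
                for j in range(truth.width):
                    alpha = jitter_concentration * truth.probs[:, j] + 0.1
                    probs[:, j] = rng.dirichlet(alpha)
            else:
                probs = truth.probs.copy()
            motifs.append(
                MotifRecord(
                    id=f"fam{fi}_motif{mi}",
                    matrix=FrequencyMatrix(probs=probs),
                    nsites=nsites,
                    coverage=1.0,
                    source_set=f"family_{fi}",
                )
            )
            labels.append(fi)
    return motifs, labels
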