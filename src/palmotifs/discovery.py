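"""Palindrome-constrained EM motif discovery and exact-p-value PWM scanning.

Discovery fits a two-component mixture to every length-W window of the
input upstream sequences: a window is either background (iid, uniform) or
an occurrence of the motif, with a Bernoulli site indicator per window
("any number of repetitions" semantics — a sequence may carry zero, one
or several sites).  EM alternates posterior site probabilities (E-step)
with a weighted-count PWM update (M-step).  When the palindrome
constraint is on, the M-step pools the weighted counts with their reverse
complement, which is the exact maximiser within the self-reverse-
complementary PWM family — so the EM objective remains monotone and every
returned motif is exactly palindromic.

Scanning scores windows by log2(p[b,j] / 0.25) summed over positions and
converts scores to exact p-values under the iid uniform null via dynamic
programming over integer-discretised column scores (FIMO-style).

The model-fitting surface follows the estimator/results convention:
``MotifDiscoveryModel(sequences, config).fit()`` returns a
``MotifDiscoveryResults`` whose ``summary()`` tabulates each motif's
width, site count, coverage and fit diagnostics.  ``discover_motifs`` is
the equivalent one-call functional form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrix import (
    BASES,
    COMPLEMENT_ROWS,
    CountMatrix,
    FrequencyMatrix,
    MotifRecord,
    information_content,
)
from .sequence_io import UpstreamSet

logger = logging.getLogger(__name__)

#: Score discretisation for the p-value DP, in bits per granule.
SCORE_GRANULARITY = 1e-3
#: Per-column floor on log-odds, in bits (guards zero-probability cells).
LOG_ODDS_FLOOR = -32.0

_N_CODE = 4  # integer code for any non-ACGT character


# ---------------------------------------------------------------------------
# configuration and hit records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscoveryConfig:
    """Parameters of the discovery stage.

    Defaults mirror the standard command line for dimeric-regulator
    operator hunting: widths 15-25, any-number-of-repetitions site model,
    palindrome constraint on, three motifs per sequence set.
    """

    min_width: int = 15
    max_width: int = 25
    n_motifs: int = 3
    site_model: str = "anr"
    palindrome: bool = True
    max_em_iters: int = 200
    em_tol: float = 1e-4
    n_starts: int = 5
    seed: int = 0
    pseudocount: float = 0.5

    def __post_init__(self):
        if not 1 <= self.min_width <= self.max_width:
            raise ValueError("need 1 <= min_width <= max_width")
        if self.n_motifs < 1:
            raise ValueError("n_motifs must be >= 1")
        if self.site_model != "anr":
            raise ValueError("only the 'anr' site model is supported")


@dataclass(frozen=True)
class MotifHit:
    """One scanner match: where, which strand, how strong, how surprising."""

    sequence_id: str
    start: int
    stop: int  # 0-based half-open
    strand: str
    score: float
    pvalue: float


# ---------------------------------------------------------------------------
# sequence encoding
# ---------------------------------------------------------------------------

_ENCODE = np.full(256, _N_CODE, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else -> 4 (treated as unknown)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# exact p-values by dynamic programming
# ---------------------------------------------------------------------------

def log_odds_matrix(pwm: FrequencyMatrix) -> np.ndarray:
    """Per-cell log2(p / 0.25), floored at LOG_ODDS_FLOOR bits."""
    with np.errstate(divide="ignore"):
        lo = np.log2(np.maximum(pwm.probs, 0.0) / 0.25)
    return np.maximum(lo, LOG_ODDS_FLOOR)


class ScoreDistribution:
    """Exact null distribution of the PWM log-odds score.

    Column scores are rounded to integer granules (SCORE_GRANULARITY
    bits); the distribution of the total over W independent uniform
    bases is then built column by column.  ``pvalue(s)`` is
    P(S >= s) under that null, non-increasing in s.
    """

    def __init__(self, pwm: FrequencyMatrix):
        self.granularity = SCORE_GRANULARITY
        lo = log_odds_matrix(pwm)
        self.int_scores = np.rint(lo / self.granularity).astype(np.int64)
        col_min = self.int_scores.min(axis=0)
        col_max = self.int_scores.max(axis=0)
        self.smin = int(col_min.sum())
        self.smax = int(col_max.sum())
        dist = np.ones(1)
        lo_off = 0  # current dist[0] corresponds to integer score lo_off
        for j in range(pwm.width):
            width = col_max[j] - col_min[j]
            new = np.zeros(dist.size + width)
            for b in range(4):
                shift = self.int_scores[b, j] - col_min[j]
                new[shift: shift + dist.size] += 0.25 * dist
            dist = new
            lo_off += int(col_min[j])
        assert lo_off == self.smin and dist.size == self.smax - self.smin + 1
        # survival function over integer scores: sf[i] = P(S_int >= smin + i)
        self.sf = np.cumsum(dist[::-1])[::-1]

    def pvalue_int(self, int_score) -> np.ndarray | float:
        """P(S >= score) for integer-granule scores (vectorised)."""
        idx = np.clip(np.asarray(int_score) - self.smin, 0, self.sf.size - 1)
        pv = self.sf[idx]
        pv = np.where(np.asarray(int_score) > self.smax, 0.0, pv)
        pv = np.where(np.asarray(int_score) <= self.smin, 1.0, pv)
        return pv if pv.ndim else float(pv)

    def pvalue(self, score: float) -> float:
        """P(S >= score) for a real-valued score in bits."""
        int_score = int(np.ceil(score / self.granularity - 1e-9))
        return float(self.pvalue_int(int_score))


def score_pvalue(pwm: FrequencyMatrix, score: float) -> float:
    """Exact P(S >= score) under the iid uniform background (one-shot form).

    Builds the DP table for ``pwm`` and evaluates one score; use
    ``ScoreDistribution`` directly to amortise the table over many scores.
    """
    return ScoreDistribution(pwm).pvalue(score)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _windows_int_scores(encoded: np.ndarray, int_scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer window scores for one encoded sequence; returns (scores, valid)."""
    w = int_scores.shape[1]
    wins = np.lib.stride_tricks.sliding_window_view(encoded, w)
    valid = (wins != _N_CODE).all(axis=1)
    safe = np.where(wins == _N_CODE, 0, wins)
    scores = int_scores[safe, np.arange(w)].sum(axis=1)
    return scores, valid


def scan(
    pwm: FrequencyMatrix,
    sequences: UpstreamSet,
    pvalue_thresh: float = 5e-5,
    norc: bool = True,
) -> list[MotifHit]:
    """Scan sequences for PWM matches with p-value <= ``pvalue_thresh``.

    With ``norc`` (the default) only the given strand is scanned,
    mirroring single-strand promoter scanning; with ``norc=False`` the
    reverse strand is scanned too and minus-strand hits are reported in
    forward-strand coordinates.  Windows overlapping non-ACGT characters
    are skipped with a warning.
    """
    w = pwm.width
    dist = ScoreDistribution(pwm)
    strands: list[tuple[str, np.ndarray]] = [("+", dist.int_scores)]
    if not norc:
        strands.append(("-", dist.int_scores[COMPLEMENT_ROWS][:, ::-1]))
    hits: list[MotifHit] = []
    for rec in sequences:
        if len(rec.sequence) < w:
            continue
        enc = encode_sequence(rec.sequence)
        n_skipped = 0
        for strand, int_scores in strands:
            scores, valid = _windows_int_scores(enc, int_scores)
            if strand == "+":
                n_skipped = int((~valid).sum())
            pv = dist.pvalue_int(scores)
            keep = valid & (pv <= pvalue_thresh)
            for start in np.nonzero(keep)[0]:
                hits.append(
                    MotifHit(
                        sequence_id=rec.gene_id,
                        start=int(start),
                        stop=int(start) + w,
                        strand=strand,
                        score=float(scores[start] * dist.granularity),
                        pvalue=float(pv[start]),
                    )
                )
        if n_skipped:
            logger.warning(
                "sequence %s: %d window(s) overlapping non-ACGT characters skipped",
                rec.gene_id, n_skipped,
            )
    hits.sort(key=lambda h: (h.sequence_id, h.start, h.strand))
    return hits


def write_hits_tsv(hits: list[MotifHit], path) -> None:
    """Hit table with FIMO-like columns; coordinates 0-based half-open."""
    df = pd.DataFrame(
        [(h.sequence_id, h.start, h.stop, h.strand, h.score, h.pvalue) for h in hits],
        columns=["sequence_id", "start", "stop", "strand", "score", "p-value"],
    )
    with open(path, "w") as fh:
        fh.write("# coordinates are 0-based half-open on the forward strand\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# EM discovery
# ---------------------------------------------------------------------------

@dataclass
class _EMFit:
    pwm: np.ndarray  # 4 x W probabilities
    gamma: float
    objective: float
    criterion: float  # penalised log-likelihood ratio used for model choice
    objective_history: list[float]
    n_iter: int
    converged: bool


def _symmetrise_counts(counts: np.ndarray) -> np.ndarray:
    return 0.5 * (counts + counts[COMPLEMENT_ROWS][:, ::-1])


def _run_em(
    windows: np.ndarray,
    pwm0: np.ndarray,
    config: DiscoveryConfig,
    max_iters: int | None = None,
    gamma0: float | None = None,
) -> _EMFit:
    """EM on a fixed window set. ``windows`` is (M, W) int in 0..3."""
    if max_iters is None:
        max_iters = config.max_em_iters
    m, w = windows.shape
    cols = np.arange(w)
    pwm = pwm0.copy()
    alpha = config.pseudocount
    # weak prior: a few sites per hundred windows
    gamma = min(0.05, 2.0 / w) if gamma0 is None else gamma0
    history: list[float] = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iters + 1):
        log_ratio = np.log(pwm / 0.25)  # natural log; pwm > 0 by pseudocount
        s = log_ratio[windows, cols].sum(axis=1)
        # posterior site probability per window
        log_odds_post = np.log(gamma) - np.log1p(-gamma) + s
        z = 1.0 / (1.0 + np.exp(-log_odds_post))
        # objective: mixture log-likelihood ratio + Dirichlet(alpha) log-prior
        ll = np.logaddexp(np.log1p(-gamma), np.log(gamma) + s).sum()
        obj = ll + alpha * np.log(pwm).sum()
        history.append(float(obj))
        if obj - prev < config.em_tol * (1.0 + abs(obj)) and it > 1:
            converged = True
            break
        prev = obj
        # M-step
        counts = np.empty((4, w))
        for j in range(w):
            counts[:, j] = np.bincount(windows[:, j], weights=z, minlength=4)
        if config.palindrome:
            counts = _symmetrise_counts(counts)
        counts += alpha
        pwm = counts / counts.sum(axis=0, keepdims=True)
        gamma = float(np.clip(z.mean(), 1e-9, 0.5))
    # final E-step quantities for reporting
    log_ratio = np.log(pwm / 0.25)
    s = log_ratio[windows, cols].sum(axis=1)
    llr = float(np.logaddexp(np.log1p(-gamma), np.log(gamma) + s).sum())
    criterion = llr - 0.5 * (3 * w + 1) * np.log(m)
    return _EMFit(
        pwm=pwm, gamma=gamma, objective=history[-1], criterion=float(criterion),
        objective_history=history, n_iter=it, converged=converged,
    )


def _site_criterion(
    encoded: list[np.ndarray],
    calls: list[tuple[int, int, float]],
    pwm: np.ndarray,
    width: int,
    n_windows: int,
) -> float:
    """Penalised log-likelihood ratio of the called (non-overlapping)
    sites: sum of per-site log ratios minus a per-free-parameter
    penalty.  Used to pick the best candidate across widths."""
    log_ratio = np.log(pwm / 0.25)
    cols = np.arange(width)
    total = 0.0
    for si, off, _ in calls:
        total += float(log_ratio[encoded[si][off: off + width], cols].sum())
    return total - 0.5 * (3 * width + 1) * np.log(max(n_windows, 2))


def _hard_restart_pwm(
    encoded: list[np.ndarray],
    calls: list[tuple[int, int, float]],
    width: int,
    config: DiscoveryConfig,
) -> np.ndarray:
    """PWM from hard counts of the called sites (sharpening restart)."""
    counts = np.zeros((4, width))
    cols = np.arange(width)
    for si, off, _ in calls:
        counts[encoded[si][off: off + width], cols] += 1
    if config.palindrome:
        counts = _symmetrise_counts(counts)
    counts += config.pseudocount
    return counts / counts.sum(axis=0, keepdims=True)


def _kmer_position_scores(encoded: list[np.ndarray], k: int) -> list[np.ndarray]:
    """Per-position k-mer enrichment score (log observed/expected count).

    Positions whose k-mer overlaps a non-ACGT character score -inf.
    """
    powers = 4 ** np.arange(k - 1, -1, -1)
    codes_per_seq: list[np.ndarray] = []
    valid_per_seq: list[np.ndarray] = []
    total = np.zeros(4 ** k)
    base_counts = np.zeros(4)
    n_bases = 0
    for enc in encoded:
        if enc.size < k:
            codes_per_seq.append(np.empty(0, dtype=np.int64))
            valid_per_seq.append(np.empty(0, dtype=bool))
            continue
        wins = np.lib.stride_tricks.sliding_window_view(enc, k)
        valid = (wins != _N_CODE).all(axis=1)
        safe = np.where(wins == _N_CODE, 0, wins).astype(np.int64)
        codes = safe @ powers
        codes_per_seq.append(codes)
        valid_per_seq.append(valid)
        total += np.bincount(codes[valid], minlength=4 ** k)
        ok = enc[enc != _N_CODE]
        base_counts += np.bincount(ok, minlength=4)
        n_bases += ok.size
    base_p = base_counts / max(n_bases, 1)
    base_p = np.clip(base_p, 1e-6, None)
    # expected count of each k-mer under the iid composition
    log_p = np.log(base_p)
    digit_logp = np.zeros(4 ** k)
    codes_all = np.arange(4 ** k)
    for i in range(k):
        digit_logp += log_p[(codes_all // (4 ** i)) % 4]
    expected = total.sum() * np.exp(digit_logp)
    kmer_score = np.log((total + 1.0) / (expected + 1.0))
    out = []
    for codes, valid in zip(codes_per_seq, valid_per_seq):
        sc = np.where(valid, kmer_score[codes], -np.inf)
        out.append(sc)
    return out


def _select_seed_windows(
    encoded: list[np.ndarray],
    kscores: list[np.ndarray],
    width: int,
    k: int,
    n_starts: int,
) -> list[tuple[int, int]]:
    """Pick diversified (sequence index, offset) seeds by summed k-mer
    enrichment over the window, greedily avoiding overlaps."""
    candidates: list[tuple[float, int, int]] = []
    for si, (enc, ks) in enumerate(zip(encoded, kscores)):
        n_off = enc.size - width + 1
        if n_off <= 0 or ks.size == 0:
            continue
        n_kpos = width - k + 1
        if ks.size < n_kpos:
            continue
        finite = np.where(np.isfinite(ks), ks, 0.0)
        csum = np.concatenate([[0.0], np.cumsum(finite)])
        scores = csum[n_kpos:n_kpos + n_off] - csum[:n_off]
        bad = np.lib.stride_tricks.sliding_window_view(~np.isfinite(ks), n_kpos).any(axis=1)
        scores = np.where(bad[:n_off], -np.inf, scores[:n_off])
        top = np.argsort(scores)[::-1][: 4 * n_starts]
        for off in top:
            if np.isfinite(scores[off]):
                candidates.append((float(scores[off]), si, int(off)))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    chosen: list[tuple[int, int]] = []
    for _, si, off in candidates:
        if len(chosen) >= n_starts:
            break
        if any(si == cs and abs(off - co) < width // 2 for cs, co in chosen):
            continue
        chosen.append((si, off))
    return chosen


def _seed_pwm(window: np.ndarray, palindrome: bool) -> np.ndarray:
    w = window.size
    pwm = np.full((4, w), 0.1)
    pwm[window, np.arange(w)] = 0.7
    if palindrome:
        pwm = 0.5 * (pwm + pwm[COMPLEMENT_ROWS][:, ::-1])
    return pwm


def _call_sites(
    encoded: list[np.ndarray],
    ids: list[str],
    pwm: np.ndarray,
    gamma: float,
    width: int,
) -> list[tuple[int, int, float]]:
    """Posterior >= 0.5 site calls, greedy non-overlapping within a sequence.

    Returns (sequence index, offset, posterior) triples in scan order.
    """
    log_ratio = np.log(pwm / 0.25)
    cols = np.arange(width)
    calls: list[tuple[int, int, float]] = []
    for si, enc in enumerate(encoded):
        if enc.size < width:
            continue
        wins = np.lib.stride_tricks.sliding_window_view(enc, width)
        valid = (wins != _N_CODE).all(axis=1)
        safe = np.where(wins == _N_CODE, 0, wins)
        s = log_ratio[safe, cols].sum(axis=1)
        z = 1.0 / (1.0 + np.exp(-(np.log(gamma) - np.log1p(-gamma) + s)))
        z = np.where(valid, z, 0.0)
        order = np.argsort(z)[::-1]
        taken: list[int] = []
        for off in order:
            if z[off] < 0.5:
                break
            if any(abs(off - t) < width for t in taken):
                continue
            taken.append(int(off))
        for off in sorted(taken):
            calls.append((si, off, float(z[off])))
    return calls


class MotifDiscoveryModel:
    """Palindrome-constrained mixture model for motif discovery.

    Parameters
    ----------
    sequences : UpstreamSet
        The upstream regions to search.
    config : DiscoveryConfig, optional
        Discovery parameters; keyword overrides are applied on top.

    ``fit()`` runs seeding + EM over every width in
    [min_width, max_width], selects candidates by a penalised
    log-likelihood-ratio criterion, masks the sites of each accepted
    motif and repeats up to ``n_motifs`` times.
    """

    def __init__(self, sequences: UpstreamSet, config: DiscoveryConfig | None = None, **overrides):
        self.sequences = sequences
        cfg = config or DiscoveryConfig()
        if overrides:
            cfg = replace(cfg, **overrides)
        self.config = cfg
        if len(sequences) < 2:
            raise ValueError("discovery needs at least 2 sequences")
        for rec in sequences:
            if len(rec.sequence) < cfg.min_width:
                raise ValueError(
                    f"sequence {rec.gene_id} shorter than min_width={cfg.min_width}"
                )

    def fit(self) -> "MotifDiscoveryResults":
        cfg = self.config
        ids = [r.gene_id for r in self.sequences]
        working = [encode_sequence(r.sequence).copy() for r in self.sequences]
        n_seqs = len(working)
        motifs: list[MotifRecord] = []
        diagnostics: list[dict] = []
        for motif_idx in range(cfg.n_motifs):
            k = min(6, cfg.min_width)
            kscores = _kmer_position_scores(working, k)
            best: _EMFit | None = None
            best_width = 0
            best_calls: list[tuple[int, int, float]] = []
            best_crit = -np.inf
            for width in range(cfg.min_width, cfg.max_width + 1):
                # pooled valid windows across sequences
                win_list = []
                for enc in working:
                    if enc.size < width:
                        continue
                    wins = np.lib.stride_tricks.sliding_window_view(enc, width)
                    ok = (wins != _N_CODE).all(axis=1)
                    if ok.any():
                        win_list.append(wins[ok])
                if not win_list:
                    continue
                windows = np.vstack(win_list).astype(np.intp)
                n_windows = windows.shape[0]
                seeds = _select_seed_windows(
                    working, kscores, width, k, 3 * cfg.n_starts
                )
                # scout every candidate seed briefly on a window subsample,
                # then refine only the most promising one on all windows
                scout_windows = windows[::3] if n_windows > 3000 else windows
                scouts = [
                    _run_em(
                        scout_windows,
                        _seed_pwm(working[si][off: off + width], cfg.palindrome),
                        cfg,
                        max_iters=12,
                    )
                    for si, off in seeds
                ]
                if not scouts:
                    continue

                # every estimator state is judged the same way: by the
                # penalised log-likelihood ratio of its non-overlapping
                # called sites.  This keeps diffuse composition-like
                # patterns (strong on the window sum, weak per site) and
                # blurred shift-averaged motifs from outranking the
                # sharp solution.
                def evaluate(pwm: np.ndarray, gamma: float):
                    calls_c = _call_sites(working, ids, pwm, gamma, width)
                    crit_c = _site_criterion(working, calls_c, pwm, width, n_windows)
                    return calls_c, crit_c

                scored = [(evaluate(s.pwm, s.gamma), s) for s in scouts]
                (top_calls, top_crit), top = max(
                    scored, key=lambda t: t[0][1]
                )
                candidates = [(top_crit, top.pwm, top_calls, top)]
                fit = _run_em(windows, top.pwm, cfg, gamma0=top.gamma)
                fit_calls, fit_crit = evaluate(fit.pwm, fit.gamma)
                candidates.append((fit_crit, fit.pwm, fit_calls, fit))
                # sharpening restart from hard counts of the confident
                # calls of the best state so far: lifts EM out of blurred
                # local optima with softened half-sites
                anchor_calls = max(candidates, key=lambda c: c[0])[2]
                confident = [c for c in anchor_calls if c[2] >= 0.99]
                restart_calls = confident if len(confident) >= 10 else anchor_calls
                if restart_calls:
                    hard_pwm = _hard_restart_pwm(working, restart_calls, width, cfg)
                    hard_gamma = max(len(restart_calls) / n_windows, 1e-6)
                    hard_calls, hard_crit = evaluate(hard_pwm, hard_gamma)
                    candidates.append((hard_crit, hard_pwm, hard_calls, fit))
                    refit = _run_em(windows, hard_pwm, cfg, gamma0=hard_gamma)
                    refit_calls, refit_crit = evaluate(refit.pwm, refit.gamma)
                    candidates.append((refit_crit, refit.pwm, refit_calls, refit))
                crit, pwm_w, calls_w, fit_w = max(candidates, key=lambda c: c[0])
                if best is None or crit > best_crit:
                    best = replace(fit_w, pwm=pwm_w)
                    best_width, best_calls, best_crit = width, calls_w, crit
            if best is None or best_crit <= 0 or not best_calls:
                break
            calls = best_calls
            site_triples = [(ids[si], off, "+") for si, off, _ in calls]
            site_windows = np.array(
                [working[si][off: off + best_width] for si, off, _ in calls]
            )
            counts = np.zeros((4, best_width))
            for j in range(best_width):
                counts[:, j] = np.bincount(site_windows[:, j], minlength=4)
            count_matrix = CountMatrix(counts=counts, nsites=len(calls))
            coverage = len({si for si, _, _ in calls}) / n_seqs
            record = MotifRecord(
                id=f"motif_{motif_idx + 1}",
                matrix=FrequencyMatrix(probs=best.pwm, pseudocount=cfg.pseudocount),
                nsites=len(calls),
                coverage=coverage,
                source_set=self.sequences.name,
                count_matrix=count_matrix,
                sites=site_triples,
            )
            motifs.append(record)
            diagnostics.append(
                {
                    "id": record.id,
                    "width": best_width,
                    "nsites": record.nsites,
                    "coverage": coverage,
                    "gamma": best.gamma,
                    "criterion": best_crit,
                    "em_llr": best.criterion,
                    "n_iter": best.n_iter,
                    "converged": best.converged,
                    "objective_history": best.objective_history,
                }
            )
            # mask found sites so later motifs cannot rediscover them
            for si, off, _ in calls:
                working[si][off: off + best_width] = _N_CODE
        return MotifDiscoveryResults(model=self, motifs=motifs, diagnostics=diagnostics)


@dataclass
class MotifDiscoveryResults:
    """Fitted motifs plus per-motif EM diagnostics."""

    model: MotifDiscoveryModel
    motifs: list[MotifRecord]
    diagnostics: list[dict] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = []
        for rec, d in zip(self.motifs, self.diagnostics):
            ic = information_content(rec.matrix)
            rows.append(
                {
                    "motif": rec.id,
                    "width": rec.width,
                    "nsites": rec.nsites,
                    "coverage": round(rec.coverage, 4),
                    "mean_ic_bits": round(ic.mean(), 4),
                    "criterion": round(d["criterion"], 2),
                    "em_iters": d["n_iter"],
                    "converged": d["converged"],
                }
            )
        return pd.DataFrame(rows)


def discover_motifs(
    sequences: UpstreamSet, config: DiscoveryConfig | None = None, **overrides
) -> list[MotifRecord]:
    """One-call discovery: fit the mixture model and return the motifs."""
    return MotifDiscoveryModel(sequences, config, **overrides).fit().motifs


def filter_motifs(
    motifs: list[MotifRecord],
    min_sites: int = 50,
    min_coverage: float = 0.75,
    min_mean_ic: float = 0.5,
) -> list[MotifRecord]:
    """Discard weakly supported motifs.

    A motif survives only with at least ``min_sites`` sites, coverage of
    at least ``min_coverage`` of the input sequences, and mean
    information content of at least ``min_mean_ic`` bits (the
    conservation requirement).  Order is preserved.
    """
    kept = []
    for m in motifs:
        if m.nsites < min_sites:
            continue
        if m.coverage < min_coverage:
            continue
        if information_content(m.matrix).mean() < min_mean_ic:
            continue
        kept.append(m)
    return kept
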