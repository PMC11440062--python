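"""Motif enrichment, position weight matrices and kinase matching.

Motif discovery follows the greedy iterative (motif-x-style) scheme: at each
step the (offset, residue) cell whose foreground count is most improbably
large under the background cell frequency (exact binomial tail) is fixed,
both window sets are filtered to the windows carrying it, and the step
repeats; when no further cell passes the E-value and support thresholds the
accumulated constraint set is emitted as one degenerate motif, its
foreground matches are removed, and the search restarts on the remainder.

Position weight matrices are per-column residue relative frequencies over
the 20-letter alphabet; terminus pads and the unknown residue ``X`` carry no
sequence evidence and are excluded from both numerator and denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._alphabet import AA20, PAD, UNKNOWN

logger = logging.getLogger("phosmap")

__all__ = [
    "MotifResult",
    "PWM",
    "enrich_motifs",
    "compute_pwm",
    "pwm_similarity",
    "rank_kinases_by_pwm",
    "residue_frequency_test",
]


@dataclass(frozen=True)
class MotifResult:
    """One enriched degenerate motif.

    ``constraints`` are (offset-from-centre, residue) pairs; counts refer to
    the foreground/background sets at the start of this motif's search round.
    """

    constraints: tuple[tuple[int, str], ...]
    fg_matches: int
    fg_size: int
    bg_matches: int
    bg_size: int
    fold_enrichment: float
    p_value: float
    e_value: float
    step_p_values: tuple[float, ...] = ()

    def pattern(self, halfwidth: int) -> str:
        """Render as dash-separated notation, e.g. ``x-R-x-x-S`` style."""
        by_offset = dict(self.constraints)
        tokens = []
        lo = min(min(by_offset), 0)
        hi = max(max(by_offset), 0)
        for off in range(lo, hi + 1):
            if off == 0:
                tokens.append("S/T/Y" if 0 not in by_offset else by_offset[0])
            else:
                tokens.append(by_offset.get(off, "x"))
        return "-".join(tokens)


@dataclass(frozen=True)
class PWM:
    """Column-normalised position weight matrix.

    ``matrix`` has shape ``(20, width)``: rows follow :data:`AA20`, columns
    are window positions; every column sums to 1.
    """

    matrix: np.ndarray
    pseudocount: float = 0.0
    alphabet: str = AA20

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def __post_init__(self) -> None:
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if (self.matrix < 0).any():
            raise ValueError("PWM entries must be nonnegative")


def _to_char_array(windows: Sequence[str]) -> np.ndarray:
    if not windows:
        raise ValueError("empty window list")
    width = len(windows[0])
    if any(len(w) != width for w in windows):
        raise ValueError("all windows must share one width")
    if width % 2 != 1:
        raise ValueError("window width must be odd (common centre)")
    return np.array([list(w) for w in windows], dtype="<U1")


def _cell_counts(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per (column, residue) counts and per-column valid (non-pad, non-X) totals."""
    width = arr.shape[1]
    counts = np.zeros((width, len(AA20)), dtype=np.int64)
    for ri, res in enumerate(AA20):
        counts[:, ri] = (arr == res).sum(axis=0)
    valid = counts.sum(axis=1)
    return counts, valid


def enrich_motifs(
    foreground: Sequence[str],
    background: Sequence[str],
    e_threshold: float = 0.01,
    min_occ: int = 10,
    max_depth: int = 5,
    max_motifs: int = 50,
    min_bg_size: int = 100,
) -> list[MotifResult]:
    """Greedy iterative motif enrichment on two window sets.

    A candidate cell's p-value is the exact binomial upper tail
    ``P(X >= k)`` for ``k`` foreground windows carrying the residue at the
    offset, out of ``n`` foreground windows with sequence evidence there, at
    the background cell frequency; its E-value applies a Bonferroni factor
    of ``(width - 1) * 20`` over all testable cells.  A cell is fixed only
    if ``e_value < e_threshold`` and ``k >= min_occ``.  Ties break toward
    the smaller \\|offset\\| and then the alphabetically smaller residue.

    The binomial tail takes the background cell frequency as exact, which is
    anticonservative when the background is not much larger than the
    foreground (a foreground-up / background-down fluctuation at any cell
    mimics enrichment).  Each candidate must therefore also pass a one-sided
    hypergeometric (Fisher) comparison of the two counts — which models both
    sampling noises — at the same corrected threshold before it is fixed;
    the reported ``p_value``/``e_value`` remain the classic binomial ones.

    Refinement beyond the first fixed cell additionally requires the
    filtered background to retain at least ``min_bg_size`` windows: with a
    handful of background windows the cell frequencies are too noisy to
    support further conditioning, and the recursion stops instead of fixing
    spurious secondary constraints.
    """
    fg_arr = _to_char_array(foreground)
    bg_arr = _to_char_array(background)
    if fg_arr.shape[1] != bg_arr.shape[1]:
        raise ValueError("foreground and background window widths differ")
    width = fg_arr.shape[1]
    centre = width // 2
    n_cells = (width - 1) * len(AA20)

    results: list[MotifResult] = []
    remaining = fg_arr
    while len(remaining) > 0 and len(results) < max_motifs:
        cur_fg = remaining
        cur_bg = bg_arr
        round_fg_size = len(cur_fg)
        constraints: list[tuple[int, str]] = []
        step_ps: list[float] = []
        while (
            len(constraints) < max_depth
            and len(cur_bg) > 0
            and (not constraints or len(cur_bg) >= min_bg_size)
        ):
            fg_counts, fg_valid = _cell_counts(cur_fg)
            bg_counts, bg_valid = _cell_counts(cur_bg)
            best = None  # (p, |offset|, offset, residue, col, ri, k)
            taken = {(off, res) for off, res in constraints}
            for col in range(width):
                if col == centre:
                    continue
                off = col - centre
                n = int(fg_valid[col])
                if n == 0 or bg_valid[col] == 0:
                    continue
                for ri, res in enumerate(AA20):
                    if (off, res) in taken:
                        continue
                    k = int(fg_counts[col, ri])
                    if k < min_occ:
                        continue
                    p_bg = bg_counts[col, ri] / bg_valid[col]
                    if p_bg == 0.0:
                        # absent from background: floor the frequency rather
                        # than report p = 0
                        p_bg = 1.0 / (bg_valid[col] + 1.0)
                    pval = float(stats.binom.sf(k - 1, n, p_bg))
                    key = (pval, abs(off), off, res)
                    if best is None or key < best[:4]:
                        best = (pval, abs(off), off, res, col, ri, k)
            if best is None:
                break
            pval, _, off, res, col, ri, k = best
            e_val = pval * n_cells
            if e_val >= e_threshold:
                break
            # background-noise-robust gate: hypergeometric tail on the
            # pooled counts must clear the same corrected threshold
            k_bg = int(bg_counts[col, ri])
            n_fg_v, n_bg_v = int(fg_valid[col]), int(bg_valid[col])
            fisher_p = float(
                stats.hypergeom.sf(k - 1, n_fg_v + n_bg_v, k + k_bg, n_fg_v)
            )
            if fisher_p * n_cells >= e_threshold:
                break
            constraints.append((off, res))
            step_ps.append(pval)
            cur_fg = cur_fg[cur_fg[:, col] == res]
            cur_bg = cur_bg[cur_bg[:, col] == res]
        if not constraints:
            break
        fg_matches = len(cur_fg)
        bg_matches = len(cur_bg)
        fg_rate = fg_matches / round_fg_size
        bg_rate = bg_matches / len(bg_arr) if len(bg_arr) else 0.0
        p_val = max(step_ps)
        results.append(
            MotifResult(
                constraints=tuple(constraints),
                fg_matches=fg_matches,
                fg_size=round_fg_size,
                bg_matches=bg_matches,
                bg_size=len(bg_arr),
                fold_enrichment=fg_rate / bg_rate if bg_rate > 0 else np.inf,
                p_value=p_val,
                e_value=p_val * n_cells,
                step_p_values=tuple(step_ps),
            )
        )
        # drop matched foreground windows and restart
        mask = np.ones(len(remaining), dtype=bool)
        for off, res in constraints:
            mask &= remaining[:, off + centre] == res
        remaining = remaining[~mask]
    return results


def compute_pwm(windows: Sequence[str], pseudocount: float = 0.0) -> PWM:
    """Per-column residue relative frequencies with an optional pseudocount.

    Pads and ``X`` are excluded from the column denominators; a column with
    no sequence evidence at all (and zero pseudocount) becomes uniform.
    """
    arr = _to_char_array(windows)
    width = arr.shape[1]
    counts = np.zeros((len(AA20), width), dtype=float)
    for ri, res in enumerate(AA20):
        counts[ri] = (arr == res).sum(axis=0)
    counts += pseudocount
    totals = counts.sum(axis=0)
    matrix = np.empty_like(counts)
    for j in range(width):
        if totals[j] == 0:
            matrix[:, j] = 1.0 / len(AA20)
        else:
            matrix[:, j] = counts[:, j] / totals[j]
    return PWM(matrix=matrix, pseudocount=pseudocount)


def pwm_similarity(pwm_a: PWM, pwm_b: PWM, metric: str = "pearson") -> float:
    """Similarity between two equal-shape PWMs.

    ``pearson`` (default): Pearson correlation of the flattened matrices,
    in [-1, 1].  ``column-euclidean``: ``1 - mean_j ||a_j - b_j|| / sqrt(2)``,
    which is 1 for identical matrices and decreases with per-column distance.
    """
    if pwm_a.matrix.shape != pwm_b.matrix.shape:
        raise ValueError("PWM shapes differ")
    if metric == "pearson":
        a = pwm_a.matrix.ravel()
        b = pwm_b.matrix.ravel()
        if np.std(a) == 0 or np.std(b) == 0:
            raise ValueError("zero-variance PWM has no Pearson correlation")
        return float(np.corrcoef(a, b)[0, 1])
    if metric == "column-euclidean":
        d = np.linalg.norm(pwm_a.matrix - pwm_b.matrix, axis=0)
        return float(1.0 - d.mean() / np.sqrt(2.0))
    raise ValueError(f"unknown PWM similarity metric {metric!r}")


def rank_kinases_by_pwm(
    site_windows: Sequence[str],
    kinase_library: Mapping[str, Sequence[str]],
    min_substrates: int = 5,
    pseudocount: float = 0.0,
    metric: str = "pearson",
) -> list[tuple[str, float]]:
    """Rank kinases by PWM similarity to the windows of one site.

    The query PWM comes from ``site_windows`` (typically the site's windows
    gathered across species); each kinase's PWM comes from its substrate
    windows.  Kinases with fewer than ``min_substrates`` windows are skipped
    with a warning.  Output is sorted by descending similarity, ties broken
    alphabetically.
    """
    if not kinase_library:
        raise ValueError("empty kinase library")
    query = compute_pwm(site_windows, pseudocount)
    ranked: list[tuple[str, float]] = []
    for kinase, windows in kinase_library.items():
        if len(windows) < min_substrates:
            logger.warning(
                "kinase %s skipped: %d substrate windows < min_substrates=%d",
                kinase, len(windows), min_substrates,
            )
            continue
        sim = pwm_similarity(query, compute_pwm(windows, pseudocount), metric)
        ranked.append((kinase, sim))
    ranked.sort(key=lambda kv: (-kv[1], kv[0]))
    return ranked


def residue_frequency_test(
    foreground: Sequence[str],
    background: Sequence[str],
    n_reference_sets: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-(offset, residue) frequency significance against sampled references.

    For each cell, ``n_reference_sets`` background resamples (with replacement) of size
    \\|foreground\\| form a sampling distribution of the cell frequency; the
    observed foreground frequency is scored as
    ``t = (obs - mean_ref) / sd_ref`` against a t distribution with
    ``n_reference_sets - 1`` degrees of freedom (two-sided).  Cells with
    ``p < alpha`` are flagged, with direction enriched/depleted.
    """
    fg_arr = _to_char_array(foreground)
    bg_arr = _to_char_array(background)
    if fg_arr.shape[1] != bg_arr.shape[1]:
        raise ValueError("foreground and background window widths differ")
    if len(fg_arr) < 10:
        raise ValueError("foreground must hold at least 10 windows")
    rng = np.random.default_rng(seed)
    width = fg_arr.shape[1]
    centre = width // 2
    n_fg = len(fg_arr)

    def freqs(arr: np.ndarray) -> np.ndarray:
        counts, valid = _cell_counts(arr)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = counts / valid[:, None]
        return np.nan_to_num(f)

    obs = freqs(fg_arr)
    ref = np.empty((n_reference_sets, width, len(AA20)))
    for r in range(n_reference_sets):
        idx = rng.choice(len(bg_arr), size=n_fg, replace=True)
        ref[r] = freqs(bg_arr[idx])
    mean_ref = ref.mean(axis=0)
    sd_ref = ref.std(axis=0, ddof=1)

    rows = []
    df = n_reference_sets - 1
    for col in range(width):
        for ri, res in enumerate(AA20):
            o, m, s = obs[col, ri], mean_ref[col, ri], sd_ref[col, ri]
            if s == 0:
                p = 1.0 if o == m else 0.0
            else:
                p = float(2.0 * stats.t.sf(abs((o - m) / s), df))
            rows.append(
                {
                    "offset": col - centre,
                    "residue": res,
                    "fg_freq": o,
                    "bg_freq": m,
                    "direction": "enriched" if o > m else ("depleted" if o < m else "equal"),
                    "p": p,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)
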