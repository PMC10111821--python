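"""Ploidy estimation from the allele balance at heterozygous sites.

A k-ploid individual carrying a heterozygous variant at dosage i shows an
alternative-allele read fraction (allele balance, AB) concentrated near
i/k, so the AB density over many heterozygous sites has modes at
{i/k : i = 1..k-1}: a single 0.50 peak for diploids, 0.25/0.50/0.75 for
tetraploids, 0.17/0.33/0.50/0.67/0.83 for hexaploids.  Real samples also
show a broad low-balance secondary mode (roughly 0.05-0.25) attributed to
collapsed repeats and segmental duplications; mode matching treats it as
a flagged nuisance, not as counter-evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import argrelextrema

from .io_formats import IntervalSet, VariantRecord

__all__ = [
    "AlleleBalanceProfile",
    "PloidyCall",
    "LowBalanceClassification",
    "allele_balance",
    "expected_peaks",
    "profile_from_records",
    "detect_modes",
    "call_ploidy",
    "classify_low_balance",
]

KDE_BANDWIDTH = 0.02
KDE_GRID_POINTS = 512
MIN_REL_DENSITY = 0.1
LOW_BALANCE_WINDOW = (0.05, 0.25)  # a stricter 0.20 upper bound is also in use
SECONDARY_WINDOW = (0.05, 0.25)
# a mode inside the secondary window only joins template matching when its
# height is comparable to the main peaks: the repeat-driven secondary peak
# is characteristically low and broad, while a genuine tetraploid 0.25 or
# hexaploid 0.17 peak carries nearly full height
SECONDARY_MAX_REL_HEIGHT = 0.6


@dataclass
class AlleleBalanceProfile:
    """Per-sample allele balances at heterozygous biallelic sites."""

    sample: str
    sites: list[tuple[str, int]]  # (chrom, pos), aligned with ab
    ab: np.ndarray  # values strictly inside (0, 1)

    def __post_init__(self) -> None:
        self.ab = np.asarray(self.ab, dtype=float)
        if self.ab.size and (self.ab.min() <= 0.0 or self.ab.max() >= 1.0):
            raise ValueError("allele balance values must lie strictly in (0, 1)")

    def __len__(self) -> int:
        return self.ab.size


@dataclass
class Mode:
    position: float
    rel_height: float  # height / max height


@dataclass
class PloidyCall:
    ploidy: Optional[int]
    modes: list[Mode]
    template: list[float]
    matched: int
    fit_score: float  # mean |mode - template| over matched pairs
    secondary_mode: bool  # unmatched mode in the low-balance window
    diagnostics: str = ""


@dataclass
class LowBalanceClassification:
    sample: str
    n_selected: int
    n_in_repeats: int
    n_in_genes: int
    pct_in_repeats: float
    pct_in_genes: float
    genes_hit: list[str]


def allele_balance(ad: Sequence[int]) -> float:
    """AB = alt depth / (ref depth + alt depth) for a biallelic AD pair."""
    ref_d, alt_d = int(ad[0]), int(ad[1])
    total = ref_d + alt_d
    if total <= 0:
        raise ValueError("no_coverage")
    return alt_d / total


def expected_peaks(k: int) -> list[float]:
    """The AB mode template {i/k : i = 1..k-1} for a k-ploid."""
    if k < 2:
        raise ValueError(f"ploidy must be >= 2, got {k}")
    return [i / k for i in range(1, k)]


def profile_from_records(records, sample: str,
                         chrom_whitelist: Optional[Sequence[str]] = None,
                         ) -> AlleleBalanceProfile:
    """Collect AB values for one sample over biallelic heterozygous calls.

    A site contributes iff the call is heterozygous, AD is present and
    0 < alt depth < total depth (AB of exactly 0 or 1 contradicts a het
    call and is excluded).
    """
    whitelist = set(chrom_whitelist) if chrom_whitelist is not None else None
    sites: list[tuple[str, int]] = []
    values: list[float] = []
    for rec in records:
        if not rec.is_biallelic:
            continue
        if whitelist is not None and rec.chrom not in whitelist:
            continue
        call = rec.calls.get(sample)
        if call is None or not call.is_het() or call.ad is None:
            continue
        ref_d, alt_d = call.ad[0], call.ad[1]
        total = ref_d + alt_d
        if total <= 0 or alt_d <= 0 or alt_d >= total:
            continue
        sites.append((rec.chrom, rec.pos))
        values.append(alt_d / total)
    return AlleleBalanceProfile(sample=sample, sites=sites,
                                ab=np.asarray(values, dtype=float))


def _kde_on_grid(values: np.ndarray, bandwidth: float, grid: np.ndarray,
                 chunk: int = 8192) -> np.ndarray:
    """Gaussian KDE with an absolute bandwidth, evaluated exactly on a grid."""
    density = np.zeros_like(grid)
    inv = 1.0 / bandwidth
    for start in range(0, values.size, chunk):
        block = values[start:start + chunk, None]
        z = (grid[None, :] - block) * inv
        density += np.exp(-0.5 * z * z).sum(axis=0)
    density *= inv / (np.sqrt(2.0 * np.pi) * values.size)
    return density


def detect_modes(profile: AlleleBalanceProfile, bandwidth: float = KDE_BANDWIDTH,
                 min_rel_density: float = MIN_REL_DENSITY) -> list[Mode]:
    """Local maxima of the AB kernel density estimate.

    The KDE uses a Gaussian kernel with the given absolute bandwidth on a
    fixed 512-point grid over (0, 1); modes below ``min_rel_density``
    times the global maximum are discarded.  The result is invariant to
    the input order of sites.
    """
    if len(profile) == 0:
        raise ValueError("no_het_sites")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    if not (0 <= min_rel_density < 1):
        raise ValueError("min_rel_density must be in [0, 1)")
    grid = np.linspace(0.0, 1.0, KDE_GRID_POINTS + 2)[1:-1]
    density = _kde_on_grid(np.sort(profile.ab), bandwidth, grid)
    peak_idx = argrelextrema(density, np.greater)[0]
    if density.size >= 2:  # grid endpoints can host modes too
        if density[0] > density[1]:
            peak_idx = np.concatenate(([0], peak_idx))
        if density[-1] > density[-2]:
            peak_idx = np.concatenate((peak_idx, [density.size - 1]))
    if peak_idx.size == 0:
        peak_idx = np.array([int(np.argmax(density))])
    max_h = density[peak_idx].max()
    modes = [
        Mode(position=float(grid[i]), rel_height=float(density[i] / max_h))
        for i in sorted(peak_idx.tolist())
        if density[i] >= min_rel_density * max_h
    ]
    return modes


def _greedy_match(mode_pos: list[float], template: list[float], tol: float,
                  ) -> tuple[list[tuple[float, float]], list[float]]:
    """Match detected modes to template peaks, closest pairs first."""
    pairs = sorted(
        ((abs(m - t), m, t) for m in mode_pos for t in template),
        key=lambda x: x[0],
    )
    used_m: set[float] = set()
    used_t: set[float] = set()
    matched: list[tuple[float, float]] = []
    for d, m, t in pairs:
        if d > tol or m in used_m or t in used_t:
            continue
        matched.append((m, t))
        used_m.add(m)
        used_t.add(t)
    unmatched = [m for m in mode_pos if m not in used_m]
    return matched, unmatched


def call_ploidy(modes: Sequence[Mode], candidates: Sequence[int] = (2, 4, 6),
                tol: float = 0.05) -> PloidyCall:
    """Pick the ploidy whose expected peak template explains the most modes.

    Ties on the matched-peak count break toward the lower mean absolute
    deviation of matched pairs, then toward the smaller ploidy.  Low,
    broad modes inside the low-balance window [0.05, 0.25) — the
    repeat-region secondary peak seen even in diploids — are withheld
    from matching and set the secondary-mode flag instead of counting as
    evidence for or against any candidate; a full-height mode in that
    window (a genuine tetraploid 0.25 or hexaploid 0.17 peak) matches
    normally.
    """
    if not modes:
        raise ValueError("no modes supplied")
    if not (0 < tol <= 0.1):
        raise ValueError("tol must be in (0, 0.1]")
    lo, hi = SECONDARY_WINDOW
    nuisance = [m.position for m in modes
                if lo <= m.position < hi
                and m.rel_height < SECONDARY_MAX_REL_HEIGHT]
    mode_pos = [m.position for m in modes if m.position not in nuisance]
    best = None
    for k in sorted(candidates):
        template = expected_peaks(k)
        matched, unmatched = _greedy_match(mode_pos, template, tol)
        if not matched:
            continue
        mad = float(np.mean([abs(m - t) for m, t in matched]))
        key = (-len(matched), mad, k)
        if best is None or key < best[0]:
            best = (key, k, template, matched, unmatched, mad)
    if best is None:
        return PloidyCall(
            ploidy=None, modes=list(modes), template=[], matched=0,
            fit_score=float("nan"), secondary_mode=False,
            diagnostics="no candidate template matches any detected mode "
                        f"within tol={tol}",
        )
    _, k, template, matched, unmatched, mad = best
    secondary = any(lo <= m < hi for m in unmatched + nuisance)
    return PloidyCall(
        ploidy=k, modes=list(modes), template=template, matched=len(matched),
        fit_score=mad, secondary_mode=secondary,
    )


def plot_profile(profile: AlleleBalanceProfile, path: str,
                 bandwidth: float = KDE_BANDWIDTH,
                 call: Optional[PloidyCall] = None) -> None:
    """Write the per-sample AB density plot (histogram + KDE + template)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = np.linspace(0.0, 1.0, KDE_GRID_POINTS + 2)[1:-1]
    density = _kde_on_grid(np.sort(profile.ab), bandwidth, grid)
    fig, ax = plt.subplots(figsize=(6, 3.2))
    ax.hist(profile.ab, bins=100, range=(0, 1), density=True,
            color="#c5cae9", label="allele balance")
    ax.plot(grid, density, color="#303f9f", lw=1.5, label="KDE")
    if call is not None and call.template:
        for t in call.template:
            ax.axvline(t, color="#d32f2f", ls="--", lw=0.8)
        ax.set_title(f"{profile.sample}: called {call.ploidy}x")
    else:
        ax.set_title(profile.sample)
    ax.set_xlabel("alternative-allele balance")
    ax.set_ylabel("density")
    ax.set_xlim(0, 1)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def classify_low_balance(profile: AlleleBalanceProfile,
                         window: tuple[float, float],
                         repeats: Optional[IntervalSet],
                         genes: Optional[IntervalSet],
                         ) -> LowBalanceClassification:
    """Tally low-balance positions against repeat and gene annotations.

    Positions with ``lo <= ab <= hi`` are mapped independently to the two
    interval sets (a position inside both counts in both); percentages
    are relative to the number of selected positions.
    """
    lo, hi = window
    if not (0 <= lo < hi <= 1):
        raise ValueError("window must satisfy 0 <= lo < hi <= 1")
    mask = (profile.ab >= lo) & (profile.ab <= hi)
    selected = [profile.sites[i] for i in np.flatnonzero(mask)]
    n_rep = n_gene = 0
    genes_hit: set[str] = set()
    for chrom, pos in selected:
        if repeats is not None and repeats.contains(chrom, pos):
            n_rep += 1
        if genes is not None and genes.contains(chrom, pos):
            n_gene += 1
            genes_hit.update(genes.names_at(chrom, pos))
    n = len(selected)
    return LowBalanceClassification(
        sample=profile.sample,
        n_selected=n,
        n_in_repeats=n_rep,
        n_in_genes=n_gene,
        pct_in_repeats=100.0 * n_rep / n if n else 0.0,
        pct_in_genes=100.0 * n_gene / n if n else 0.0,
        genes_hit=sorted(genes_hit),
    )
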