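"""Polarity-invariant modified K-means, GEV, and KL-GEV model-order selection.

Microstate templates are cluster centres of GFP-peak topographies under a
polarity-invariant metric: a map ``x`` is assigned to the template ``a_k``
minimising the orthogonal squared distance ``d^2 = x'x - (x'a_k)^2``
(templates unit-norm), i.e. maximising the squared spatial correlation, so a
map and its sign-flip land in the same class.

Model order is chosen from the global explained variance (GEV) curve: with
``g(K) = K^(2/C) * GEV_K``, the interval-2 increment ``DIFF_K = g(K) -
g(K-2)`` and the ratio ``KL_K = DIFF_K / DIFF_{K+2}`` locate the elbow of
the GEV curve; the largest interior local peak of the KL series is the
selected number of microstates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import NoPeakError, ValidationError
from .gfp import TopographyBank

logger = logging.getLogger(__name__)

__all__ = [
    "TemplateSet",
    "ModelOrderScan",
    "ClusterConfig",
    "spatial_correlation",
    "assign_maps",
    "gev",
    "modified_kmeans",
    "klgev_criterion",
    "select_k_optimal",
    "scan_and_select",
]


@dataclass
class TemplateSet:
    """K microstate template maps plus the fit on the bank they came from.

    Rows of ``templates`` are zero-mean, unit-norm; ``labels_of_bank`` are
    1-based class labels for the clustered bank; ``gev_per_class`` sums to
    ``gev_total``.
    """

    templates: np.ndarray
    labels_of_bank: np.ndarray
    gev_total: float
    gev_per_class: np.ndarray
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.templates = np.atleast_2d(np.asarray(self.templates, dtype=float))
        self.labels_of_bank = np.asarray(self.labels_of_bank, dtype=int)
        self.gev_per_class = np.asarray(self.gev_per_class, dtype=float)
        if np.max(np.abs(self.templates.mean(axis=1))) > 1e-8:
            raise ValidationError("templates must be zero-mean (average-referenced)")
        norms = np.linalg.norm(self.templates, axis=1)
        if np.max(np.abs(norms - 1)) > 1e-6:
            raise ValidationError("templates must be unit-norm")
        if not -1e-9 <= self.gev_total <= 1 + 1e-9:
            raise ValidationError("total GEV must lie in [0, 1]")
        if abs(self.gev_per_class.sum() - self.gev_total) > 1e-6:
            raise ValidationError("per-class GEV must sum to the total")

    @property
    def K(self) -> int:
        return self.templates.shape[0]

    @property
    def n_channels(self) -> int:
        return self.templates.shape[1]


@dataclass
class ModelOrderScan:
    """Per-K criterion series and the selected model order.

    ``diff_by_k[K]`` exists only when ``K-2`` is in the grid; ``kl_by_k[K]``
    only when both ``DIFF_K`` and ``DIFF_{K+2}`` exist.  ``k_optimal`` may be
    ``None`` until selection has run.
    """

    k_grid: list[int]
    C: int
    gev_by_k: dict[int, float]
    norm_gev_by_k: dict[int, float] = field(default_factory=dict)
    diff_by_k: dict[int, float] = field(default_factory=dict)
    kl_by_k: dict[int, float] = field(default_factory=dict)
    k_optimal: int | None = None

    def as_table(self):
        """Scan as a tidy DataFrame with columns K, GEV, normGEV, DIFF, KL."""
        import pandas as pd

        rows = []
        for k in self.k_grid:
            rows.append(
                {
                    "K": k,
                    "GEV": self.gev_by_k.get(k, np.nan),
                    "normGEV": self.norm_gev_by_k.get(k, np.nan),
                    "DIFF": self.diff_by_k.get(k, np.nan),
                    "KL": self.kl_by_k.get(k, np.nan),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class ClusterConfig:
    """Modified K-means settings; all randomness flows from ``seed``."""

    max_iter: int = 100
    restarts: int = 20
    seed: int = 0
    tol: float = 0.0
    align_mode: str = "sign_aligned_mean"

    def __post_init__(self) -> None:
        if self.max_iter < 1 or self.restarts < 1 or self.tol < 0:
            raise ValidationError("max_iter, restarts >= 1 and tol >= 0 required")
        if self.align_mode not in ("sign_aligned_mean", "literal_mean"):
            raise ValidationError(f"unknown align_mode {self.align_mode!r}")


def spatial_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Uncentered cosine similarity between two maps.

    On average-referenced maps this equals the Pearson spatial correlation
    coefficient used throughout microstate analysis.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValidationError("maps must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValidationError("spatial correlation undefined for a zero map")
    return float(np.dot(u, v) / (nu * nv))


def _corr_matrix(maps: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Signed correlation of every map with every unit-norm template."""
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    safe = np.where(norms == 0, 1.0, norms)
    return (maps @ templates.T) / safe


def assign_maps(bank: TopographyBank | np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Polarity-invariant nearest-template labels (1-based).

    Minimising ``d^2 = x'x - (x'a_k)^2`` is equivalent to maximising the
    squared projection on unit-norm templates; ties break to the smallest k.
    """
    maps = bank.maps if isinstance(bank, TopographyBank) else np.atleast_2d(bank)
    templates = np.atleast_2d(templates)
    if maps.shape[1] != templates.shape[1]:
        raise ValidationError("map and template channel counts differ")
    proj = maps @ templates.T
    return np.argmax(proj**2, axis=1) + 1


def gev(
    maps: np.ndarray,
    gfp_values: np.ndarray,
    templates: np.ndarray,
    labels: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Global explained variance, total and per class.

    ``GEV_n = Corr(x_n, a_{l_n})^2 * GFP_n^2 / sum_n' GFP_n'^2``; per-class
    values sum members, the total sums classes.  Labels are 1-based.
    """
    maps = np.atleast_2d(maps)
    templates = np.atleast_2d(templates)
    gfp_values = np.asarray(gfp_values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    K = templates.shape[0]
    if labels.min() < 1 or labels.max() > K:
        raise ValidationError("labels must lie in 1..K")
    denom = float(np.sum(gfp_values**2))
    if denom == 0:
        raise ValidationError("all-zero GFP: GEV undefined")
    corr = _corr_matrix(maps, templates)
    picked = corr[np.arange(maps.shape[0]), labels - 1]
    gev_n = picked**2 * gfp_values**2 / denom
    per_class = np.array(
        [float(gev_n[labels == k].sum()) for k in range(1, K + 1)]
    )
    return float(per_class.sum()), per_class


def _recalc_centers(
    maps: np.ndarray,
    labels: np.ndarray,
    templates: np.ndarray,
    align_mode: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Cluster-centre update.

    The centre is the mathematical average of the member maps; under
    polarity-invariant assignment opposite-polarity members would cancel in
    a literal average, so by default each member is sign-aligned with the
    current centre first.  Centres are re-centred (zero mean) and unit
    normalised.  An empty cluster is re-seeded from the worst-fitting map.
    """
    K, C = templates.shape
    new = np.empty_like(templates)
    proj = maps @ templates.T
    d2 = np.sum(maps**2, axis=1, keepdims=True) - proj**2
    fit_of_assigned = d2[np.arange(maps.shape[0]), labels - 1]
    for k in range(1, K + 1):
        members = maps[labels == k]
        if members.shape[0] == 0:
            worst = int(np.argmax(fit_of_assigned))
            center = maps[worst].copy()
            logger.debug("re-seeding empty cluster %d from map %d", k, worst)
        elif align_mode == "sign_aligned_mean":
            signs = np.sign(members @ templates[k - 1])
            signs[signs == 0] = 1.0
            center = (members * signs[:, None]).mean(axis=0)
        else:
            center = members.mean(axis=0)
        center = center - center.mean()
        norm = np.linalg.norm(center)
        if norm == 0:  # cancelled average: re-seed randomly from members
            idx = int(rng.integers(maps.shape[0]))
            center = maps[idx] - maps[idx].mean()
            norm = np.linalg.norm(center)
        new[k - 1] = center / norm
    return new


def modified_kmeans(
    bank: TopographyBank, K: int, cfg: ClusterConfig | None = None
) -> TemplateSet:
    """Cluster the topography bank into K polarity-invariant templates.

    Alternates assignment and centre recalculation until the labels stop
    changing or ``max_iter`` is reached; the best of ``restarts`` seeded
    random initialisations (centres drawn from the bank) by total GEV is
    returned.  ``K = 1`` is permitted (single-template fit, used by scans
    that need a GEV value at the grid edge).
    """
    cfg = cfg or ClusterConfig()
    maps = bank.maps
    M = maps.shape[0]
    if K < 1:
        raise ValidationError("K must be >= 1")
    if K > M:
        raise ValidationError(f"K={K} exceeds the number of bank maps M={M}")
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.restarts)
    best: tuple[float, np.ndarray, np.ndarray, np.ndarray] | None = None
    for ss in seeds:
        rng = np.random.default_rng(ss)
        init_idx = rng.choice(M, size=K, replace=False)
        templates = maps[init_idx].astype(float).copy()
        templates -= templates.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(templates, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        templates /= norms
        labels = assign_maps(maps, templates)
        for _ in range(cfg.max_iter):
            templates = _recalc_centers(maps, labels, templates, cfg.align_mode, rng)
            new_labels = assign_maps(maps, templates)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
        total, per_class = gev(maps, bank.gfp_at_peak, templates, labels)
        if best is None or total > best[0]:
            best = (total, templates, labels, per_class)
    total, templates, labels, per_class = best
    return TemplateSet(templates, labels, total, per_class, bank.channel_names)


def klgev_criterion(
    gev_by_k: dict[int, float], C: int, k_grid: list[int] | None = None
) -> ModelOrderScan:
    """Derive the normalised-GEV, DIFF and KL series from a GEV curve.

    ``norm(K) = K^(2/C) * GEV_K``; ``DIFF_K = norm(K) - norm(K-2)`` wherever
    ``K-2`` is on the grid; ``KL_K = DIFF_K / DIFF_{K+2}`` wherever both
    increments exist (a zero ``DIFF_{K+2}`` leaves that entry undefined).
    """
    if C < 2:
        raise ValidationError("channel count must be >= 2")
    grid = sorted(k_grid) if k_grid is not None else sorted(gev_by_k)
    if len(grid) < 2 or any(b - a != 1 for a, b in zip(grid, grid[1:])):
        raise ValidationError("k_grid must be contiguous with step 1")
    if grid[-1] - grid[0] < 5:
        raise ValidationError("k_grid must span at least 5 (need defined KL entries)")
    missing = [k for k in grid if k not in gev_by_k]
    if missing:
        raise ValidationError(f"GEV missing for K in {missing}")
    scan = ModelOrderScan(k_grid=grid, C=C, gev_by_k=dict(gev_by_k))
    for k in grid:
        scan.norm_gev_by_k[k] = k ** (2.0 / C) * gev_by_k[k]
    for k in grid:
        if k - 2 in scan.norm_gev_by_k:
            scan.diff_by_k[k] = scan.norm_gev_by_k[k] - scan.norm_gev_by_k[k - 2]
    for k in grid:
        if k in scan.diff_by_k and k + 2 in scan.diff_by_k:
            denom = scan.diff_by_k[k + 2]
            if denom == 0:
                logger.warning("DIFF_%d = 0: KL_%d undefined", k + 2, k)
                continue
            scan.kl_by_k[k] = scan.diff_by_k[k] / denom
    return scan


def select_k_optimal(scan: ModelOrderScan) -> int:
    """Largest interior local peak of the KL series.

    Among K whose immediate neighbours in the defined KL series exist and
    satisfy ``KL[K] > KL[K-1]`` and ``KL[K] > KL[K+1]``, the K with the
    largest KL wins (ties to the smallest K).  Endpoints of the defined
    series are never eligible; an empty peak set raises :class:`NoPeakError`.
    """
    ks = sorted(scan.kl_by_k)
    if len(ks) < 3:
        raise NoPeakError("KL series has fewer than 3 defined entries")
    peaks = [
        k
        for prev, k, nxt in zip(ks, ks[1:], ks[2:])
        if scan.kl_by_k[k] > scan.kl_by_k[prev] and scan.kl_by_k[k] > scan.kl_by_k[nxt]
    ]
    if not peaks:
        raise NoPeakError(
            "no interior local peak in the KL series; widen the K grid"
        )
    best = max(peaks, key=lambda k: (scan.kl_by_k[k], -k))
    scan.k_optimal = int(best)
    return scan.k_optimal


def scan_and_select(
    bank: TopographyBank,
    k_min: int = 2,
    k_max: int = 17,
    cfg: ClusterConfig | None = None,
) -> tuple[ModelOrderScan, TemplateSet]:
    """Cluster the bank for every K on the grid and pick the model order.

    Returns the scan plus the (already fitted, not re-fit) template set at
    the selected K.  ``k_min`` may be 1 so that a small true K can sit
    interior to the defined KL series.
    """
    if k_min < 1:
        raise ValidationError("k_min must be >= 1")
    if k_max - k_min < 4:
        raise ValidationError("k grid must span at least 5 values")
    cfg = cfg or ClusterConfig()
    gev_by_k: dict[int, float] = {}
    fits: dict[int, TemplateSet] = {}
    child_seeds = np.random.SeedSequence(cfg.seed).spawn(k_max - k_min + 1)
    for i, k in enumerate(range(k_min, k_max + 1)):
        k_cfg = ClusterConfig(
            max_iter=cfg.max_iter,
            restarts=cfg.restarts,
            seed=int(child_seeds[i].generate_state(1)[0] % (2**31)),
            tol=cfg.tol,
            align_mode=cfg.align_mode,
        )
        fit = modified_kmeans(bank, k, k_cfg)
        gev_by_k[k] = fit.gev_total
        fits[k] = fit
        logger.debug("K=%d: GEV=%.4f", k, fit.gev_total)
    scan = klgev_criterion(gev_by_k, bank.n_channels)
    select_k_optimal(scan)
    return scan, fits[scan.k_optimal]
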