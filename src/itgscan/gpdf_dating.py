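"""Sequence-identity distributions, density peaks, and divergence dating.

Pairwise identities between homologous sequences are pooled into an
identity dataset (one value per unordered pair, best hit kept), smoothed
with a Gaussian-kernel density estimate on a fixed identity grid, and the
local maxima of the density are converted to divergence times with the
molecular-clock relation

    T = Ks / (2 r),    Ks = 1 − (identity peak value),

where r is the nucleotide substitution rate per site per year (default
1.5e-8). No multiple-hit (e.g. Jukes–Cantor) correction is applied: Ks is
the raw identity complement, so the relation holds only for Ks well below
saturation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.signal
import scipy.stats
from Bio import Align

from .genomic_io import HomologyHit

logger = logging.getLogger("itgscan")


@dataclass(frozen=True)
class DatingConfig:
    r: float = 1.5e-8  # substitutions per site per year
    e_threshold: float = 1e-5
    bandwidth: float | str = "auto"  # identity units, or "auto" (Silverman)
    min_peak_prominence: float = 0.05  # fraction of max density
    grid_step: float = 0.001

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError(f"substitution rate must be positive, got {self.r}")
        if self.e_threshold <= 0:
            raise ValueError("e_threshold must be positive")
        if self.bandwidth != "auto" and float(self.bandwidth) <= 0:
            raise ValueError("bandwidth must be positive or 'auto'")


@dataclass(frozen=True)
class IdentityDataset:
    """Identity fractions in [0, 1], one per unordered sequence pair."""

    values: np.ndarray
    provenance: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size and (v.min() < 0.0 or v.max() > 1.0):
            raise ValueError("identity values must lie in [0, 1]")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class DensityCurve:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float


@dataclass(frozen=True)
class IdentityPeak:
    """A local maximum of the identity density, with its derived age."""

    identity: float
    density: float
    ks: float
    time_years: float

    @classmethod
    def at(cls, identity: float, density: float, r: float) -> "IdentityPeak":
        return cls(identity, density, 1.0 - identity, divergence_time(identity, r))


def divergence_time(identity: float, r: float) -> float:
    """T = Ks / (2r) with Ks = 1 − identity; identity in [0, 1], r > 0."""
    if not 0.0 <= identity <= 1.0:
        raise ValueError(f"identity must be in [0, 1], got {identity}")
    if r <= 0:
        raise ValueError(f"substitution rate must be positive, got {r}")
    return (1.0 - identity) / (2.0 * r)


def build_identity_dataset(
    hits: Iterable[HomologyHit], cfg: DatingConfig = DatingConfig()
) -> IdentityDataset:
    """Pool hits into one identity value per unordered sequence pair.

    Self-hits are removed; for each unordered pair the single best hit is
    kept (lowest e-value, ties broken by highest identity). Percent
    identities are converted to fractions.
    """
    best: dict[tuple[str, str], HomologyHit] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        key = (min(h.query_id, h.subject_id), max(h.query_id, h.subject_id))
        cur = best.get(key)
        if (
            cur is None
            or h.e_value < cur.e_value
            or (h.e_value == cur.e_value and h.pct_identity > cur.pct_identity)
        ):
            best[key] = h
    if not best:
        raise ValueError("no homologous pairs")
    keys = sorted(best)
    return IdentityDataset(
        np.array([best[k].pct_identity / 100.0 for k in keys]),
        tuple(keys),
    )


_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-2,
)


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity = matches / aligned columns (gaps included).

    Scoring: match +1, mismatch −1, gap −2 (linear). Among co-optimal
    alignments the aligner's first traceback is used.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    aln = _ALIGNER.align(a.upper(), b.upper())[0]
    c = aln.counts()
    columns = c.identities + c.mismatches + c.gaps
    return c.identities / columns


def align_all_pairs(
    seqs_a: dict[str, str], seqs_b: dict[str, str] | None = None
) -> IdentityDataset:
    """All-vs-all (or A-vs-B) pairwise identities; intended for small sets."""
    values = []
    prov = []
    if seqs_b is None:
        names = sorted(seqs_a)
        pairs = [
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]
        lookup_b = seqs_a
    else:
        pairs = [(x, y) for x in sorted(seqs_a) for y in sorted(seqs_b) if x != y]
        lookup_b = seqs_b
    for x, y in pairs:
        values.append(pairwise_identity(seqs_a[x], lookup_b[y]))
        prov.append((min(x, y), max(x, y)))
    if not values:
        raise ValueError("no homologous pairs")
    return IdentityDataset(np.array(values), tuple(prov))


def fit_gpdf(
    dataset: IdentityDataset, cfg: DatingConfig = DatingConfig()
) -> DensityCurve:
    """Gaussian-kernel density of the identity values on a fixed grid.

    Bandwidth "auto" uses Silverman's rule; a numeric bandwidth is in
    identity units. A degenerate all-equal dataset yields a single narrow
    (delta-like) peak with a warning.
    """
    v = dataset.values
    if v.size < 2:
        raise ValueError("need at least 2 identity values")
    grid = np.arange(0.0, 1.0 + cfg.grid_step / 2, cfg.grid_step)
    std = float(np.std(v))
    if std < 1e-9:  # all-equal up to float accumulation noise
        logger.warning("fit_gpdf: degenerate all-equal dataset; delta-like peak")
        bw = cfg.grid_step if cfg.bandwidth == "auto" else float(cfg.bandwidth)
        density = scipy.stats.norm.pdf(grid, loc=float(v[0]), scale=bw)
        return DensityCurve(grid, density, bw)
    if cfg.bandwidth == "auto":
        kde = scipy.stats.gaussian_kde(v, bw_method="silverman")
    else:
        kde = scipy.stats.gaussian_kde(v, bw_method=float(cfg.bandwidth) / std)
    bw = float(kde.factor * std)
    density = kde(grid)
    mass = float(np.trapezoid(density, grid))
    if abs(mass - 1.0) > 1e-3:
        logger.warning(
            "fit_gpdf: density mass on [0,1] is %.4f (edge leakage)", mass
        )
    return DensityCurve(grid, density, bw)


def find_peaks(
    curve: DensityCurve, cfg: DatingConfig = DatingConfig()
) -> list[IdentityPeak]:
    """Local density maxima with prominence ≥ min_peak_prominence × max.

    Topographic prominence alone cannot reject a flat distribution: the
    global maximum of any density has full prominence because the curve
    decays to zero outside the data support. A mode must therefore also
    stand out by the same margin above the *typical* density level (the
    median over the support, taken where density ≥ 1% of the maximum), so
    a near-uniform sample reports no peaks. Peaks are returned in
    decreasing density order.
    """
    dmax = float(curve.density.max())
    if dmax <= 0:
        return []
    baseline = float(np.median(curve.density[curve.density >= 0.01 * dmax]))
    idx, _ = scipy.signal.find_peaks(
        curve.density, prominence=cfg.min_peak_prominence * dmax
    )
    idx = [
        i for i in idx
        if curve.density[i] - baseline >= cfg.min_peak_prominence * dmax
    ]
    peaks = [
        IdentityPeak.at(float(curve.grid[i]), float(curve.density[i]), cfg.r)
        for i in idx
    ]
    peaks.sort(key=lambda p: -p.density)
    return peaks


def date_peaks(
    peaks: Sequence[IdentityPeak], cfg: DatingConfig = DatingConfig()
) -> list[dict]:
    """Tabulate peaks as identity / Ks / time rows (years and Mya)."""
    return [
        {
            "identity": p.identity,
            "density": p.density,
            "ks": p.ks,
            "time_years": p.time_years,
            "time_mya": p.time_years / 1e6,
        }
        for p in peaks
    ]


def gmm_peaks(
    dataset: IdentityDataset,
    max_components: int = 4,
    random_state: int = 0,
) -> list[float]:
    """Gaussian-mixture cross-check: component means, BIC-selected k.

    An independent route to the identity peaks, for comparison with the
    kernel-density estimate; not used by the main pipeline.
    """
    from sklearn.mixture import GaussianMixture

    x = dataset.values.reshape(-1, 1)
    best_model = None
    best_bic = np.inf
    for k in range(1, max_components + 1):
        gm = GaussianMixture(n_components=k, random_state=random_state, n_init=3)
        gm.fit(x)
        bic = gm.bic(x)
        if bic < best_bic:
            best_bic, best_model = bic, gm
    means = sorted(float(m) for m in best_model.means_.ravel())
    return means
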