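"""In vitro cleavage quantification and kinetics.

Gel densitometry enters as band-intensity tables; the cleaved fraction of a
lane is the summed product-band intensity over total lane intensity. Lanes
carrying NAAN-format PAM labels assemble into a 4x4 matrix keyed by the bases
flanking the adenine dinucleotide; time courses are fit to the standard
irreversible single-exponential model f(t) = A * (1 - exp(-k t)); replicate
series are summarized as mean +/- sample standard deviation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import InputError
from .iupac import DNA_BASES

NAAN_LENGTH = 4


@dataclass
class GelLane:
    """One gel lane: uncleaved substrate band plus zero or more product bands."""

    lane_id: str
    substrate_intensity: float
    product_intensities: list[float]
    enzyme: str = ""
    pam: str = ""
    time_min: float | None = None
    ratio: float | None = None

    def __post_init__(self):
        if self.substrate_intensity < 0 or any(p < 0 for p in self.product_intensities):
            raise InputError(f"lane {self.lane_id!r} has negative intensities")


@dataclass(frozen=True)
class CleavageMeasurement:
    """A cleaved fraction in [0, 1] with lane provenance."""

    fraction: float
    lane_id: str

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise InputError(f"fraction {self.fraction} outside [0, 1]")


@dataclass
class NaanMatrix:
    """4x4 cleaved-fraction summary keyed by (5' base, 3' base) around the
    AA dinucleotide; mean over replicates, sample sd where n >= 2."""

    mean: pd.DataFrame
    sd: pd.DataFrame
    n: pd.DataFrame
    missing: list[tuple[str, str]]


@dataclass
class TimeCourse:
    """Cleaved fraction over time (minutes), strictly increasing timepoints."""

    points: list[tuple[float, float]]
    enzyme: str = ""
    pam: str = ""

    def __post_init__(self):
        times = [t for t, _ in self.points]
        if any(t < 0 for t in times):
            raise InputError("timepoints must be nonnegative")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InputError("timepoints must be strictly increasing")
        if any(not 0.0 <= f <= 1.0 for _, f in self.points):
            raise InputError("fractions must lie in [0, 1]")


@dataclass
class KineticsFit:
    """Apparent first-order fit: rate k (per minute), plateau amplitude,
    residual sum of squares, and an honest convergence flag."""

    k: float
    plateau: float
    rss: float
    converged: bool


@dataclass
class TitrationSeries:
    """Cleaved fraction versus enzyme:target molar ratio."""

    points: list[tuple[float, float]]
    enzyme: str = ""
    pam: str = ""

    def __post_init__(self):
        if any(r <= 0 for r, _ in self.points):
            raise InputError("molar ratios must be positive")
        if any(not 0.0 <= f <= 1.0 for _, f in self.points):
            raise InputError("fractions must lie in [0, 1]")


def cleaved_fraction(lane: GelLane) -> CleavageMeasurement:
    """Sum of product bands over total lane intensity (substrate + products)."""
    products = float(sum(lane.product_intensities))
    total = products + float(lane.substrate_intensity)
    if total <= 0:
        raise InputError(f"lane {lane.lane_id!r} has zero total intensity")
    return CleavageMeasurement(fraction=products / total, lane_id=lane.lane_id)


def summarize_replicates(values: Sequence[float]) -> tuple[float, float | None]:
    """Arithmetic mean and sample standard deviation (n-1 denominator);
    sd is None for a single value."""
    if not values:
        raise InputError("no replicate values")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) >= 2 else None
    return mean, sd


def _parse_naan(pam: str) -> tuple[str, str]:
    pam = pam.upper()
    if (len(pam) != NAAN_LENGTH or pam[1:3] != "AA"
            or pam[0] not in DNA_BASES or pam[3] not in DNA_BASES):
        raise InputError(f"PAM label {pam!r} is not of NAAN form (xAAy)")
    return pam[0], pam[3]


def assemble_naan_matrix(measurements: Iterable[tuple[str, float]]) -> NaanMatrix:
    """Aggregate (PAM label, cleaved fraction) pairs into the 4x4 matrix.

    Cell (x, y) holds the replicate mean for PAM xAAy; sd uses the n-1
    denominator and is NaN below two replicates. Cells with no data are
    listed in ``missing`` (the completeness check covers all 16 keys).
    """
    cells: dict[tuple[str, str], list[float]] = {}
    for pam, fraction in measurements:
        if not 0.0 <= fraction <= 1.0:
            raise InputError(f"fraction {fraction} outside [0, 1] for PAM {pam!r}")
        cells.setdefault(_parse_naan(pam), []).append(fraction)

    bases = list(DNA_BASES)
    mean = pd.DataFrame(np.nan, index=bases, columns=bases)
    sd = pd.DataFrame(np.nan, index=bases, columns=bases)
    n = pd.DataFrame(0, index=bases, columns=bases, dtype=int)
    missing = []
    for x, y in itertools.product(bases, bases):
        vals = cells.get((x, y))
        if not vals:
            missing.append((x, y))
            continue
        m, s = summarize_replicates(vals)
        mean.loc[x, y] = m
        if s is not None:
            sd.loc[x, y] = s
        n.loc[x, y] = len(vals)
    return NaanMatrix(mean=mean, sd=sd, n=n, missing=missing)


def fit_first_order(tc: TimeCourse) -> KineticsFit:
    """Least-squares fit of f(t) = A * (1 - exp(-k t)).

    Initialization: A0 = max observed fraction, k0 = 1 / (time of first
    half-maximal point); bounds A in [0, 1.05], k >= 0. A flat time course
    short-circuits to k = 0 with converged=False (the rate is unidentified).
    """
    if len(tc.points) < 3:
        raise InputError(f"need >= 3 timepoints, got {len(tc.points)}")
    t = np.array([p[0] for p in tc.points], dtype=float)
    f = np.array([p[1] for p in tc.points], dtype=float)

    if np.allclose(f, f[0]):
        return KineticsFit(k=0.0, plateau=float(f[0]), rss=0.0, converged=False)

    a0 = max(float(f.max()), 1e-6)
    half = np.nonzero(f >= a0 / 2)[0]
    t_half = t[half[0]] if half.size and t[half[0]] > 0 else max(t[t > 0].min(), 1e-6)
    k0 = 1.0 / t_half

    def resid(params):
        a, k = params
        return a * (1.0 - np.exp(-k * t)) - f

    res = least_squares(resid, x0=[a0, k0], bounds=([0.0, 0.0], [1.05, np.inf]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    a_hat, k_hat = res.x
    return KineticsFit(k=float(k_hat), plateau=float(a_hat),
                       rss=float(np.sum(res.fun ** 2)), converged=bool(res.success))


def read_lanes_tsv(path: str | Path) -> list[GelLane]:
    """Read a lane table: lane_id, enzyme, pam, time_min, ratio, substrate,
    product_1..product_k (variable product columns; blanks allowed)."""
    df = pd.read_csv(path, sep="\t")
    required = {"lane_id", "substrate"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"lane TSV missing columns: {sorted(missing)}")
    product_cols = sorted((c for c in df.columns if c.startswith("product_")),
                          key=lambda c: int(c.split("_")[1]))
    lanes = []
    for _, row in df.iterrows():
        products = [float(row[c]) for c in product_cols if pd.notna(row[c])]
        lanes.append(GelLane(
            lane_id=str(row["lane_id"]),
            substrate_intensity=float(row["substrate"]),
            product_intensities=products,
            enzyme=str(row.get("enzyme", "") or ""),
            pam=str(row.get("pam", "") or ""),
            time_min=float(row["time_min"]) if pd.notna(row.get("time_min")) else None,
            ratio=float(row["ratio"]) if pd.notna(row.get("ratio")) else None,
        ))
    return lanes


def write_lanes_tsv(lanes: Sequence[GelLane], path: str | Path) -> None:
    k = max((len(l.product_intensities) for l in lanes), default=1)
    rows = []
    for lane in lanes:
        row = {
            "lane_id": lane.lane_id, "enzyme": lane.enzyme, "pam": lane.pam,
            "time_min": lane.time_min, "ratio": lane.ratio,
            "substrate": lane.substrate_intensity,
        }
        for i in range(k):
            row[f"product_{i + 1}"] = (lane.product_intensities[i]
                                       if i < len(lane.product_intensities) else None)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def plot_naan_heatmap(matrix: NaanMatrix, path: str | Path) -> None:
    """Render the 4x4 cleaved-fraction matrix as a heat map (PNG/PDF by suffix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(matrix.mean.to_numpy(dtype=float), vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(4), matrix.mean.columns)
    ax.set_yticks(range(4), matrix.mean.index)
    ax.set_xlabel("3' base (NAAx)")
    ax.set_ylabel("5' base (xAAN)")
    for i in range(4):
        for j in range(4):
            v = matrix.mean.iat[i, j]
            if not math.isnan(v):
                ax.text(j, i, f"{v:.2f}", ha="center", va="center",
                        color="w" if v < 0.5 else "k", fontsize=8)
    fig.colorbar(im, ax=ax, label="cleaved fraction")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
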