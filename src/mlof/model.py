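"""Empirical reference densities and the mLOF score.

The mLOF score converts two structural summaries of a variant set — EDC
(spatial clustering) and mean ΔΔG_rank (energetic impact) — into a single
probability that the set acts through loss of function.  For each metric,
Gaussian kernel densities are fitted separately to the values observed in
LOF-mechanism and non-LOF-mechanism reference genes, on a grid of 1024
equidistant points, using three times the Sheather-Jones plug-in bandwidth
(the multiplier keeps the resulting probability curves smooth and
monotone).  An observation x is first capped at empirical percentile
bounds so that extreme values cannot dominate, then scored at the nearest
grid point:

    P_LOF(x) = f_LOF(x') / (f_LOF(x') + f_non-LOF(x'))

The two marginal probabilities are combined by a case-specific weighted
mean — each metric is weighted by the evidence supporting the *other*
metric (P_LOF(EDC) by the number of variants entering mean ΔΔG_rank,
P_LOF(ΔΔG) by the number of residue positions entering EDC) — which
weakens the ΔΔG term when variants sit in disordered regions and
strengthens EDC there, and vice versa.

``MlofModel`` wraps the procedure statsmodels-style: build it from a
reference table of per-gene (EDC, mean ΔΔG_rank, class) rows, ``fit()``
returns an ``MlofResults`` object that scores observations, prints a
``summary()`` and serialises to a versioned JSON artifact.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from mlof.errors import BandwidthError, DataError, InsufficientReferenceError
from mlof.ddg import DdgRankResult
from mlof.edc import EdcResult

_SQRT_2PI = math.sqrt(2.0 * math.pi)

MODEL_FORMAT_VERSION = 1


class Metric(str, enum.Enum):
    EDC = "EDC"
    DDG_RANK = "DDG_RANK"


# ---------------------------------------------------------------------------
# Sheather-Jones solve-the-equation plug-in bandwidth
# ---------------------------------------------------------------------------

def _phi4_sum(x: np.ndarray, h: float) -> float:
    """(1/(n(n-1)h^5 sqrt(2pi))) * sum_ij phi4((xi-xj)/h), diagonal included."""
    n = x.size
    d = (x[:, None] - x[None, :]) / h
    d2 = d * d
    term = np.exp(-0.5 * d2) * (d2 * d2 - 6.0 * d2 + 3.0)
    return float(term.sum() / (n * (n - 1) * h**5 * _SQRT_2PI))


def _phi6_sum(x: np.ndarray, h: float) -> float:
    n = x.size
    d = (x[:, None] - x[None, :]) / h
    d2 = d * d
    term = np.exp(-0.5 * d2) * (d2**3 - 15.0 * d2 * d2 + 45.0 * d2 - 15.0)
    return float(term.sum() / (n * (n - 1) * h**7 * _SQRT_2PI))


def silverman_bandwidth(values) -> float:
    x = np.asarray(values, dtype=float)
    n = x.size
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale <= 0:
        raise BandwidthError("zero-variance sample")
    return 0.9 * scale * n ** (-0.2)


def sheather_jones_bandwidth(values) -> float:
    """Sheather-Jones solve-the-equation plug-in bandwidth.

    The two-stage pilot estimates and the fixed constants follow the
    classical formulation (as implemented in R's ``bw.SJ(method="ste")``):
    pilot bandwidths a = 1.24*s*n^(-1/7) and b = 1.23*s*n^(-1/9) with
    s = min(SD, IQR/1.349) feed the curvature functionals, and the final
    bandwidth solves h = (1 / (2 sqrt(pi) n SD(alpha2(h))))^(1/5).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise BandwidthError(f"need >= 2 values for bandwidth selection, got {n}")
    sd = x.std(ddof=1)
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if not np.isfinite(scale) or scale <= 0:
        raise BandwidthError("zero-variance sample")

    a = 1.24 * scale * n ** (-1.0 / 7.0)
    b = 1.23 * scale * n ** (-1.0 / 9.0)
    c1 = 1.0 / (2.0 * math.sqrt(math.pi) * n)
    td = -_phi6_sum(x, b)
    sda = _phi4_sum(x, a)
    if not np.isfinite(td) or td <= 0 or not np.isfinite(sda) or sda <= 0:
        raise BandwidthError("curvature functional not positive; sample too pathological")
    alpha2 = 1.357 * (sda / td) ** (1.0 / 7.0)

    def fsd(h: float) -> float:
        return (c1 / _phi4_sum(x, alpha2 * h ** (5.0 / 7.0))) ** 0.2 - h

    hmax = 1.144 * scale * n ** (-0.2)
    lo, hi = 0.1 * hmax, hmax
    flo, fhi = fsd(lo), fsd(hi)
    for _ in range(10):  # widen the bracket if needed
        if flo * fhi <= 0:
            break
        hi *= 2.0
        fhi = fsd(hi)
    else:
        raise BandwidthError("no bandwidth solution in the searched range")
    return float(brentq(fsd, lo, hi, xtol=1e-10))


def _class_bandwidth(values, multiplier: float) -> float:
    try:
        return multiplier * sheather_jones_bandwidth(values)
    except BandwidthError as exc:
        if "zero-variance" in str(exc) or "need >=" in str(exc):
            raise
        warnings.warn(
            f"Sheather-Jones bandwidth failed ({exc}); falling back to Silverman's rule",
            RuntimeWarning,
            stacklevel=2,
        )
        return multiplier * silverman_bandwidth(values)


def gaussian_kde_grid(values, h: float, grid: np.ndarray) -> np.ndarray:
    """Gaussian kernel density of ``values`` with bandwidth ``h`` on ``grid``."""
    x = np.asarray(values, dtype=float)
    z = (grid[:, None] - x[None, :]) / h
    return np.exp(-0.5 * z * z).sum(axis=1) / (x.size * h * _SQRT_2PI)


# ---------------------------------------------------------------------------
# Reference densities
# ---------------------------------------------------------------------------

@dataclass
class ReferenceDensity:
    """Class-conditional densities of one metric with cap bounds.

    ``cap_lof`` bounds the LOF-like tail (high mean ΔΔG_rank, low EDC) and
    ``cap_nonlof`` the non-LOF-like tail; observations beyond a cap are
    pulled back to it before scoring.
    """

    metric: Metric
    d_points: np.ndarray
    f_lof: np.ndarray
    f_nonlof: np.ndarray
    cap_lof: float
    cap_nonlof: float
    bandwidth_lof: float
    bandwidth_nonlof: float

    def __post_init__(self) -> None:
        self.metric = Metric(self.metric)
        self.d_points = np.asarray(self.d_points, dtype=float)
        self.f_lof = np.asarray(self.f_lof, dtype=float)
        self.f_nonlof = np.asarray(self.f_nonlof, dtype=float)
        steps = np.diff(self.d_points)
        if self.d_points.size >= 2 and not (
            (steps > 0).all() and np.allclose(steps, steps[0], rtol=1e-8)
        ):
            raise ValueError("d_points must be strictly increasing and equidistant")
        if (self.f_lof < 0).any() or (self.f_nonlof < 0).any():
            raise ValueError("densities must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["metric"] = self.metric.value
        for k in ("d_points", "f_lof", "f_nonlof"):
            d[k] = [float(v) for v in d[k]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceDensity":
        return cls(**d)


def fit_reference(
    lof_values,
    nonlof_values,
    metric: Metric,
    bandwidth_multiplier: float = 3.0,
    grid_n: int = 1024,
    cap_quantiles: tuple[float, float] = (0.10, 0.90),
    cap_mode: str = "class",
    min_class_size: int = 10,
    bandwidths: tuple[float, float] | None = None,
) -> ReferenceDensity:
    """Fit the LOF / non-LOF reference densities of one metric.

    Parameters
    ----------
    bandwidth_multiplier : scales the per-class Sheather-Jones bandwidth
        (default 3, which smooths the probability curve into monotonicity).
    cap_quantiles : (low, high) percentile pair defining the caps.
    cap_mode : ``"class"`` places each cap at the owning class's own tail
        percentile; ``"pooled"`` uses percentiles of the pooled sample.
    bandwidths : explicit (h_lof, h_nonlof) override, bypassing selection.
    """
    metric = Metric(metric)
    lof = np.asarray(lof_values, dtype=float)
    non = np.asarray(nonlof_values, dtype=float)
    for name, arr in (("LOF", lof), ("non-LOF", non)):
        if arr.size < min_class_size:
            raise InsufficientReferenceError(
                f"{name} class has {arr.size} values; need >= {min_class_size}"
            )
        if not np.isfinite(arr).all():
            raise ValueError(f"{name} class contains non-finite values")

    if bandwidths is not None:
        h_lof, h_non = float(bandwidths[0]), float(bandwidths[1])
    else:
        h_lof = _class_bandwidth(lof, bandwidth_multiplier)
        h_non = _class_bandwidth(non, bandwidth_multiplier)

    pooled = np.concatenate([lof, non])
    pad = 3.0 * max(h_lof, h_non)
    grid = np.linspace(pooled.min() - pad, pooled.max() + pad, grid_n)

    q_low, q_high = cap_quantiles
    if cap_mode == "class":
        # each cap sits on the tail where its class's density dominates
        if metric is Metric.DDG_RANK:  # LOF-like = high values
            cap_lof = float(np.quantile(lof, q_high))
            cap_nonlof = float(np.quantile(non, q_low))
        else:  # EDC: LOF-like = low values (dispersed variants)
            cap_lof = float(np.quantile(lof, q_low))
            cap_nonlof = float(np.quantile(non, q_high))
    elif cap_mode == "pooled":
        if metric is Metric.DDG_RANK:
            cap_lof = float(np.quantile(pooled, q_high))
            cap_nonlof = float(np.quantile(pooled, q_low))
        else:
            cap_lof = float(np.quantile(pooled, q_low))
            cap_nonlof = float(np.quantile(pooled, q_high))
    else:
        raise ValueError(f"unknown cap_mode {cap_mode!r}")

    return ReferenceDensity(
        metric=metric,
        d_points=grid,
        f_lof=gaussian_kde_grid(lof, h_lof, grid),
        f_nonlof=gaussian_kde_grid(non, h_non, grid),
        cap_lof=cap_lof,
        cap_nonlof=cap_nonlof,
        bandwidth_lof=h_lof,
        bandwidth_nonlof=h_non,
    )


def cap_observation(x: float, density: ReferenceDensity) -> float:
    """Clamp an observation at the reference cap bounds.

    For mean ΔΔG_rank the LOF-like tail is high, so values above
    ``cap_lof`` are pulled down and values below ``cap_nonlof`` up; for
    EDC the inequalities mirror (low EDC is LOF-like).
    """
    if density.metric is Metric.DDG_RANK:
        if x > density.cap_lof:
            return density.cap_lof
        if x < density.cap_nonlof:
            return density.cap_nonlof
    else:
        if x < density.cap_lof:
            return density.cap_lof
        if x > density.cap_nonlof:
            return density.cap_nonlof
    return float(x)


def p_lof(x_capped: float, density: ReferenceDensity) -> float:
    """LOF probability of a capped observation at its nearest grid point."""
    idx = int(np.argmin(np.abs(density.d_points - x_capped)))  # ties -> lower index
    fl = float(density.f_lof[idx])
    fn = float(density.f_nonlof[idx])
    if fl + fn == 0.0:
        raise DataError(
            f"{density.metric.value}: both reference densities vanish at x={x_capped!r}"
        )
    return fl / (fl + fn)


@dataclass(frozen=True)
class MlofResult:
    """Marginal LOF probabilities, their weights and the combined score."""

    p_lof_edc: float | None
    p_lof_ddg: float
    w_edc: int
    w_ddg: int
    mlof: float
    capped_edc: float | None
    capped_ddg: float
    ddg_only: bool = False


def mlof_score(
    edc_result: EdcResult | None,
    ddg_result: DdgRankResult,
    edc_density: ReferenceDensity | None,
    ddg_density: ReferenceDensity,
) -> MlofResult:
    """Combine the two marginal LOF probabilities into the mLOF score.

    The weighted mean uses w_EDC = number of variants behind mean
    ΔΔG_rank and w_ΔΔG = number of residue positions behind EDC.  When the
    EDC component is unavailable (too few structured variant positions)
    the score degrades to P_LOF(ΔΔG) alone, flagged ``ddg_only``.
    """
    x_ddg = cap_observation(ddg_result.mean_rank, ddg_density)
    p_ddg = p_lof(x_ddg, ddg_density)
    if edc_result is None or edc_density is None:
        return MlofResult(
            p_lof_edc=None, p_lof_ddg=p_ddg,
            w_edc=ddg_result.n_variants, w_ddg=0,
            mlof=p_ddg, capped_edc=None, capped_ddg=x_ddg, ddg_only=True,
        )
    x_edc = cap_observation(edc_result.edc, edc_density)
    p_edc = p_lof(x_edc, edc_density)
    w_edc = ddg_result.n_variants
    w_ddg = edc_result.n_disease_positions
    total = w_edc + w_ddg
    if total <= 0:
        raise DataError("zero total weight for the mLOF combination")
    combined = (w_edc * p_edc + w_ddg * p_ddg) / total
    return MlofResult(
        p_lof_edc=p_edc, p_lof_ddg=p_ddg, w_edc=w_edc, w_ddg=w_ddg,
        mlof=float(combined), capped_edc=x_edc, capped_ddg=x_ddg,
    )


# ---------------------------------------------------------------------------
# Model / Results wrappers
# ---------------------------------------------------------------------------

class MlofModel:
    """Reference model for the mLOF score.

    Built from a table of reference genes with known mechanism class
    (columns: gene, class in {LOF, NONLOF}, edc, mean_ddg_rank); ``fit()``
    estimates the four class-conditional densities and returns an
    :class:`MlofResults`.
    """

    CLASSES = ("LOF", "NONLOF")

    def __init__(self, data: pd.DataFrame):
        required = {"gene", "class", "edc", "mean_ddg_rank"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"reference table missing columns {sorted(missing)}")
        cls = data["class"].astype(str).str.upper().str.replace("-", "", regex=False)
        bad = set(cls) - set(self.CLASSES)
        if bad:
            raise ValueError(f"unknown mechanism classes {sorted(bad)}; expected LOF/NONLOF")
        self.data = data.assign(**{"class": cls}).reset_index(drop=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MlofModel":
        return cls(df)

    @classmethod
    def from_table(cls, path: str) -> "MlofModel":
        return cls(pd.read_csv(path, sep=None, engine="python"))

    def _split(self, column: str) -> tuple[np.ndarray, np.ndarray]:
        g = self.data.groupby("class")[column]
        return (
            g.get_group("LOF").to_numpy(dtype=float),
            g.get_group("NONLOF").to_numpy(dtype=float),
        )

    def fit(
        self,
        bandwidth_multiplier: float = 3.0,
        grid_n: int = 1024,
        cap_quantiles: tuple[float, float] = (0.10, 0.90),
        cap_mode: str = "class",
    ) -> "MlofResults":
        edc_lof, edc_non = self._split("edc")
        ddg_lof, ddg_non = self._split("mean_ddg_rank")
        common = dict(
            bandwidth_multiplier=bandwidth_multiplier,
            grid_n=grid_n,
            cap_quantiles=cap_quantiles,
            cap_mode=cap_mode,
        )
        return MlofResults(
            edc_density=fit_reference(edc_lof, edc_non, Metric.EDC, **common),
            ddg_density=fit_reference(ddg_lof, ddg_non, Metric.DDG_RANK, **common),
            n_lof=int(edc_lof.size),
            n_nonlof=int(edc_non.size),
            params=common,
            model=self,
        )


@dataclass
class MlofResults:
    """A fitted mLOF reference: densities, caps, bandwidths and scoring."""

    edc_density: ReferenceDensity
    ddg_density: ReferenceDensity
    n_lof: int
    n_nonlof: int
    params: dict = field(default_factory=dict)
    model: MlofModel | None = None

    def score(
        self, edc_result: EdcResult | None, ddg_result: DdgRankResult
    ) -> MlofResult:
        return mlof_score(edc_result, ddg_result, self.edc_density, self.ddg_density)

    def score_values(
        self,
        edc: float | None,
        mean_ddg_rank: float,
        n_variants: int,
        n_positions: int = 0,
    ) -> MlofResult:
        """Score raw (EDC, mean ΔΔG_rank) numbers with explicit weights."""
        ddg = DdgRankResult(mean_rank=float(mean_ddg_rank), n_variants=int(n_variants))
        edc_res = (
            None
            if edc is None
            else EdcResult(edc=float(edc), n_disease_positions=int(n_positions), n_residues_used=0)
        )
        return self.score(edc_res, ddg)

    def p_lof_curve(self, metric: Metric) -> tuple[np.ndarray, np.ndarray]:
        """The capped P_LOF(x) curve of one metric over its grid."""
        den = self.edc_density if Metric(metric) is Metric.EDC else self.ddg_density
        xs = den.d_points
        ps = np.array([p_lof(cap_observation(float(x), den), den) for x in xs])
        return xs, ps

    def summary(self) -> str:
        rows = []
        for den in (self.edc_density, self.ddg_density):
            rows.append(
                f"  {den.metric.value:<9s} grid [{den.d_points[0]:.4f}, {den.d_points[-1]:.4f}] "
                f"n={den.d_points.size}  h_LOF={den.bandwidth_lof:.4f} "
                f"h_nonLOF={den.bandwidth_nonlof:.4f}  caps [{min(den.cap_lof, den.cap_nonlof):.4f}, "
                f"{max(den.cap_lof, den.cap_nonlof):.4f}]"
            )
        lines = [
            "mLOF reference model",
            "====================",
            f"reference genes: {self.n_lof} LOF / {self.n_nonlof} non-LOF",
            f"bandwidth multiplier: {self.params.get('bandwidth_multiplier', 'n/a')}  "
            f"cap mode: {self.params.get('cap_mode', 'n/a')}  "
            f"cap quantiles: {self.params.get('cap_quantiles', 'n/a')}",
            *rows,
        ]
        return "\n".join(lines)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "n_lof": self.n_lof,
            "n_nonlof": self.n_nonlof,
            "params": {
                k: (list(v) if isinstance(v, tuple) else v) for k, v in self.params.items()
            },
            "edc_density": self.edc_density.to_dict(),
            "ddg_density": self.ddg_density.to_dict(),
        }

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str) -> "MlofResults":
        with open(path) as fh:
            d = json.load(fh)
        version = d.get("format_version")
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {version!r}")
        params = d.get("params", {})
        if "cap_quantiles" in params:
            params["cap_quantiles"] = tuple(params["cap_quantiles"])
        return cls(
            edc_density=ReferenceDensity.from_dict(d["edc_density"]),
            ddg_density=ReferenceDensity.from_dict(d["ddg_density"]),
            n_lof=d["n_lof"],
            n_nonlof=d["n_nonlof"],
            params=params,
        )
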