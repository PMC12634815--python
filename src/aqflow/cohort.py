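"""Synthetic cohort generation.

Generates subjects whose demographics, ventricular volumetrics,
aqueduct geometry and cardiac-gated flow waveforms carry the reported
statistical structure of the healthy and iNPH study populations: in the
healthy group the representative aqueduct velocity follows the inverse
relation U = a/D (a = 26.4 mm^2/s) plus Gaussian noise, so the maximum
Reynolds number is approximately conserved across subjects; in the iNPH
group U is drawn independently of D so that Re matches the reported
58.0 +/- 27.6 with no inverse relation.

Stroke volume is not drawn independently: each subject's waveform is
built from (U, D, T_c), making waveform, stroke volume, representative
velocity and Reynolds number mutually consistent.

Units: mm, mm/s, microlitres (= mm^3), seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm



class ParameterError(ValueError):
    """Raised for invalid or infeasible cohort parameters."""


@dataclass
class FlowWaveform:
    """One cardiac cycle of aqueduct flow rate, phase-resolved.

    times are strictly increasing within [0, period); the value at
    phase 0 is reused after one period (periodic extension).  Positive
    Q is craniocaudal flow (third -> fourth ventricle).
    """

    times: np.ndarray      # s
    flow_rate: np.ndarray  # ul/s
    period: float          # s

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.flow_rate = np.asarray(self.flow_rate, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ParameterError("waveform needs at least two phases")
        if not (np.diff(self.times) > 0).all():
            raise ParameterError("phase times must be strictly increasing")
        if self.times[0] < 0 or self.times[-1] >= self.period:
            raise ParameterError("phase times must lie in [0, period)")

    @property
    def n_phases(self) -> int:
        return self.times.size

    def closed_cycle(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and flow rates with the periodic endpoint appended."""
        t = np.append(self.times, self.times[0] + self.period)
        q = np.append(self.flow_rate, self.flow_rate[0])
        return t, q

    def net_volume(self) -> float:
        t, q = self.closed_cycle()
        return float(np.trapezoid(q, t))

    def check_zero_net(self, tol: float = 1e-6) -> None:
        t, q = self.closed_cycle()
        scale = float(np.trapezoid(np.abs(q), t))
        if scale > 0 and abs(self.net_volume()) > tol * scale:
            raise ParameterError(
                f"waveform net volume {self.net_volume():.3g} ul exceeds "
                f"tolerance {tol:g} x {scale:.3g} ul"
            )

    def sample(self, t, kind: str = "cubic"):
        """Periodic interpolation of Q at arbitrary times."""
        t = np.mod(np.asarray(t, dtype=float), self.period)
        tc, qc = self.closed_cycle()
        if kind == "linear":
            return np.interp(t, tc, qc)
        from scipy.interpolate import CubicSpline

        return CubicSpline(tc, qc, bc_type="periodic")(t)


def generate_waveform(
    stroke_volume: float,
    period: float,
    n_phases: int = 8,
    shape: str = "sinusoid",
) -> FlowWaveform:
    """Cardiac-gated flow waveform with a prescribed stroke volume.

    stroke volume is the bidirectional mean displaced volume per cycle,
    SV = 0.5 * integral |Q| dt; the returned phase samples reproduce it
    to within the quadrature error of the phase grid.  For the sinusoid
    the continuous amplitude is Q0 = SV * pi / period.
    """
    if stroke_volume < 0:
        raise ParameterError("stroke volume must be >= 0")
    if period <= 0:
        raise ParameterError("period must be positive")
    if n_phases < 4:
        raise ParameterError("need >= 4 phases to represent a bidirectional cycle")
    times = period * np.arange(n_phases) / n_phases
    if shape == "sinusoid":
        q0 = stroke_volume * np.pi / period
        q = q0 * np.sin(2.0 * np.pi * times / period)
    elif shape == "biphasic":
        tau = times / period
        unit = np.sin(2 * np.pi * tau) + 0.35 * np.sin(4 * np.pi * tau + np.pi / 4)
        td = np.linspace(0.0, 1.0, 20001)
        ud = np.sin(2 * np.pi * td) + 0.35 * np.sin(4 * np.pi * td + np.pi / 4)
        sv_unit = 0.5 * np.trapezoid(np.abs(ud), td) * period
        q = unit * (stroke_volume / sv_unit if sv_unit > 0 else 0.0)
        q = q - np.trapezoid(
            np.append(q, q[0]), np.append(times, period)
        ) / period  # remove residual DC from phase sampling
    else:
        raise ParameterError(f"unknown waveform shape {shape!r}")
    return FlowWaveform(times=times, flow_rate=q, period=period)


def waveform_peak_factor(shape: str, period: float) -> float:
    """Peak |Q| per unit stroke volume for a waveform shape."""
    wf = generate_waveform(1.0, period, 256, shape)
    return float(np.abs(wf.flow_rate).max())


@dataclass
class CohortParams:
    """Distribution parameters of one synthetic study group.

    Defaults are the printed healthy-cohort statistics; use
    ``CohortParams.inph()`` for the iNPH contrast group.  All marginals
    are independent truncated Gaussians except U, which in the healthy
    group is tied to D through U = a/D + noise.
    """

    group: str = "healthy"
    n_subjects: int = 47
    n_male: int = 19
    n_female: int = 28
    age_mean: float = 52.0
    age_sd: float = 18.0
    weight_mean: float = 60.0
    weight_sd: float = 11.0
    lv_mean: float = 23.3       # ml
    lv_sd: float = 11.8
    v3_mean: float = 1.1
    v3_sd: float = 0.5
    v4_mean: float = 1.6
    v4_sd: float = 0.3
    d_mean: float = 2.82        # mm
    d_sd: float = 0.56
    a_coef: float = 26.4        # mm^2/s, healthy inverse-relation coefficient
    u_noise_sd: float = 4.7     # mm/s, spread about U = a/D
    re_mean: float | None = None  # iNPH: Re drawn directly
    re_sd: float | None = None
    period_mean: float = 0.9    # s
    period_sd: float = 0.08
    n_phases: int = 8
    aqueduct_length: float = 12.0  # mm, not reported; template parameter
    waveform_shape: str = "sinusoid"
    seed: int = 0

    @classmethod
    def inph(cls, **kw) -> "CohortParams":
        defaults = dict(
            group="inph",
            n_subjects=10,
            n_male=6,
            n_female=4,
            age_mean=75.0,
            age_sd=7.0,
            weight_mean=56.0,
            weight_sd=12.0,
            lv_mean=109.7,
            lv_sd=32.2,
            v3_mean=4.5,
            v3_sd=1.0,
            v4_mean=3.0,
            v4_sd=1.0,
            d_mean=3.1,   # not reported for iNPH; plausible dilated aqueduct
            d_sd=0.6,
            re_mean=58.0,
            re_sd=27.6,
        )
        defaults.update(kw)
        return cls(**defaults)

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ParameterError("n_subjects must be positive")
        if self.n_male + self.n_female != self.n_subjects:
            raise ParameterError("n_subjects must equal n_male + n_female")
        if self.n_phases < 4:
            raise ParameterError("n_phases must be >= 4")
        sds = dict(
            age=self.age_sd, weight=self.weight_sd, lv=self.lv_sd, v3=self.v3_sd,
            v4=self.v4_sd, d=self.d_sd, u_noise=self.u_noise_sd,
            period=self.period_sd,
        )
        for name, sd in sds.items():
            if sd < 0:
                raise ParameterError(f"{name}_sd must be >= 0")
        for name, mean, sd, lo in [
            ("d", self.d_mean, self.d_sd, 0.0),
            ("period", self.period_mean, self.period_sd, 0.0),
            ("lv", self.lv_mean, self.lv_sd, 0.0),
            ("v3", self.v3_mean, self.v3_sd, 0.0),
            ("v4", self.v4_mean, self.v4_sd, 0.0),
        ]:
            if mean <= lo and sd == 0:
                raise ParameterError(f"{name} mean must exceed {lo}")
            if sd > 0 and (mean - lo) / sd < -8.0:
                raise ParameterError(
                    f"{name}: mean {mean} lies many SDs below the bound {lo}; "
                    "truncated sampling infeasible"
                )


@dataclass
class SubjectRecord:
    """One synthetic subject with geometry, flow descriptors and waveform."""

    id: str
    group: str
    sex: str
    age: float
    weight: float
    lv_volume: float
    v3_volume: float
    v4_volume: float
    aqueduct_diameter: float
    aqueduct_length: float
    cardiac_period: float
    velocity: float        # representative velocity U, mm/s (peak |Q|/A)
    stroke_volume: float   # ul
    waveform: FlowWaveform = field(repr=False)

    def __post_init__(self):
        if self.aqueduct_diameter <= 0 or self.cardiac_period <= 0:
            raise ParameterError("D and T_c must be positive")
        if self.stroke_volume < 0 or self.velocity < 0:
            raise ParameterError("SV and U must be non-negative")

    @property
    def area(self) -> float:
        """Nominal circular cross-section area, mm^2."""
        return math.pi * (self.aqueduct_diameter / 2.0) ** 2


def _trunc_normal(rng, mean, sd, lo, size):
    if sd == 0:
        return np.full(size, float(mean))
    a = (lo - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(params: CohortParams, seed: int | None = None) -> list[SubjectRecord]:
    """Deterministic synthetic cohort.

    Healthy subjects: U = a/D + eps, eps ~ N(0, u_noise_sd), floored at
    a small positive velocity.  iNPH subjects: Re drawn directly and
    U = Re/D (numerically Re = U*D in mm units for water-like CSF), so
    no inverse relation holds.  Stroke volume follows from (U, D, T_c)
    via the waveform shape's peak factor.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n_subjects
    age = _trunc_normal(rng, params.age_mean, params.age_sd, 18.0, n)
    weight = _trunc_normal(rng, params.weight_mean, params.weight_sd, 30.0, n)
    lv = _trunc_normal(rng, params.lv_mean, params.lv_sd, 1.0, n)
    v3 = _trunc_normal(rng, params.v3_mean, params.v3_sd, 0.05, n)
    v4 = _trunc_normal(rng, params.v4_mean, params.v4_sd, 0.05, n)
    dia = _trunc_normal(rng, params.d_mean, params.d_sd, 0.8, n)
    period = _trunc_normal(rng, params.period_mean, params.period_sd, 0.4, n)
    if params.group == "healthy" or params.re_mean is None:
        noise = rng.normal(0.0, params.u_noise_sd, n) if params.u_noise_sd > 0 else np.zeros(n)
        vel = np.maximum(params.a_coef / dia + noise, 0.1)
    else:
        re = _trunc_normal(rng, params.re_mean, params.re_sd, 1.0, n)
        vel = re / dia  # Re = U*D in mm units at CSF properties
    sexes = ["M"] * params.n_male + ["F"] * params.n_female

    prefix = "H" if params.group == "healthy" else "P"
    subjects = []
    for i in range(n):
        area = math.pi * (dia[i] / 2.0) ** 2
        peak_q = vel[i] * area
        pf = waveform_peak_factor(params.waveform_shape, period[i])
        sv = peak_q / pf
        wf = generate_waveform(sv, period[i], params.n_phases, params.waveform_shape)
        subjects.append(
            SubjectRecord(
                id=f"{prefix}{i + 1:03d}",
                group=params.group,
                sex=sexes[i],
                age=float(age[i]),
                weight=float(weight[i]),
                lv_volume=float(lv[i]),
                v3_volume=float(v3[i]),
                v4_volume=float(v4[i]),
                aqueduct_diameter=float(dia[i]),
                aqueduct_length=params.aqueduct_length,
                cardiac_period=float(period[i]),
                velocity=float(vel[i]),
                stroke_volume=float(sv),
                waveform=wf,
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# delimited-table I/O
# ---------------------------------------------------------------------------

_CSV_COLS = [
    "id", "group", "sex", "age", "weight", "lv_volume", "v3_volume", "v4_volume",
    "aqueduct_diameter", "aqueduct_length", "cardiac_period", "velocity",
    "stroke_volume",
]


def cohort_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        d = asdict(s)
        d.pop("waveform")
        rows.append(d)
    return pd.DataFrame(rows, columns=_CSV_COLS)


def write_cohort(subjects: list[SubjectRecord], outdir: str | Path) -> Path:
    """Cohort table plus one waveform CSV per subject."""
    outdir = Path(outdir)
    (outdir / "waveforms").mkdir(parents=True, exist_ok=True)
    table = cohort_frame(subjects)
    table.to_csv(outdir / "subjects.csv", index=False)
    for s in subjects:
        pd.DataFrame(
            {"time_s": s.waveform.times, "Q_ul_per_s": s.waveform.flow_rate}
        ).to_csv(outdir / "waveforms" / f"{s.id}.csv", index=False)
    return outdir / "subjects.csv"


def read_cohort(outdir: str | Path) -> list[SubjectRecord]:
    outdir = Path(outdir)
    table = pd.read_csv(outdir / "subjects.csv")
    subjects = []
    for _, row in table.iterrows():
        wf_tab = pd.read_csv(outdir / "waveforms" / f"{row['id']}.csv")
        wf = FlowWaveform(
            times=wf_tab["time_s"].to_numpy(),
            flow_rate=wf_tab["Q_ul_per_s"].to_numpy(),
            period=float(row["cardiac_period"]),
        )
        subjects.append(
            SubjectRecord(waveform=wf, **{c: row[c] for c in _CSV_COLS})
        )
    return subjects
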