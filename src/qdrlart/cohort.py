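"""Patient data model, radiomics feature math and synthetic cohorts.

A patient's state in the radiotherapy environment is a 5-feature vector:
the circulating cytokine IP10, the PET radiomics texture GLSZM-ZSV
(zone-size variance of the gray-level size-zone matrix), tumor and lung
generalized equivalent uniform dose (gEUD, in Gy), and the cxcr1-Rs2234671
SNP encoded as an allele count in {0, 1, 2}.

Real adaptive-trial cohorts are access-restricted, so this module also
provides a seeded synthetic generator that emulates the schema: a
pre-treatment observation (weeks 0-4), a mid-treatment observation after
two-thirds of the course, the clinical dose per fraction chosen for the
last third, and binary local-control (LC) / grade-2+ pneumonitis (RP2)
outcomes drawn from dose-dependent logistic probabilities so that higher
dose raises both tumor control and toxicity risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import arte as _radbio

__all__ = [
    "PatientState",
    "PatientRecord",
    "CohortConfig",
    "GLSZMatrix",
    "compute_zsv",
    "generate_cohort",
    "read_cohort",
    "write_cohort",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = [
    "patient_id",
    "ip10_pre", "zsv_pre", "tumor_geud_pre", "lung_geud_pre", "genotype",
    "ip10_mid", "zsv_mid", "tumor_geud_mid", "lung_geud_mid",
    "clinical_dose", "lc", "rp2",
]


class SchemaError(ValueError):
    """Raised when a cohort file violates the documented CSV schema."""


@dataclass(frozen=True)
class PatientState:
    """The 5-feature state vector s_t."""

    ip10: float
    glszm_zsv: float
    tumor_geud: float
    lung_geud: float
    cxcr1_genotype: int

    def __post_init__(self):
        for name in ("ip10", "glszm_zsv", "tumor_geud", "lung_geud"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.glszm_zsv < 0 or self.tumor_geud < 0 or self.lung_geud < 0:
            raise ValueError("glszm_zsv and gEUDs must be nonnegative")
        if self.cxcr1_genotype not in (0, 1, 2):
            raise ValueError(f"genotype must be in {{0,1,2}}, got {self.cxcr1_genotype!r}")

    def as_vector(self) -> np.ndarray:
        return np.array([self.ip10, self.glszm_zsv, self.tumor_geud,
                         self.lung_geud, float(self.cxcr1_genotype)])


@dataclass(frozen=True)
class PatientRecord:
    """One patient: pre/mid states, last-third clinical dose, outcomes."""

    patient_id: str
    state_pre: PatientState
    state_mid: PatientState
    clinical_dose: float  # Gy per fraction for the last treatment third
    lc: int
    rp2: int

    def __post_init__(self):
        if not self.clinical_dose > 0:
            raise ValueError("clinical_dose must be positive")
        if self.lc not in (0, 1) or self.rp2 not in (0, 1):
            raise ValueError("lc and rp2 must be binary")


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Marginals: log-normal IP10 and ZSV (positive-support biomarkers),
    truncated-normal gEUDs, Binomial(2, q) genotype allele counts.
    Outcome labels are Bernoulli draws from logistic dose-response curves
    evaluated on the end-of-treatment (week 6) gEUDs, so P(LC=1) and
    P(RP2=1) both increase with the clinical dose per fraction.
    """

    n_patients: int = 200
    seed: int = 0
    # marginals of the pre-treatment state
    ip10_log_mean: float = np.log(30.0)
    ip10_log_sd: float = 0.5
    zsv_log_mean: float = np.log(2.0)
    zsv_log_sd: float = 0.6
    tumor_geud_mean: float = 30.0
    tumor_geud_sd: float = 4.0
    lung_geud_mean: float = 10.0
    lung_geud_sd: float = 3.0
    genotype_allele_freq: float = 0.3
    # dose policy of the emulated trial
    dose_mean: float = 2.2
    dose_sd: float = 0.6
    dose_min: float = 1.0
    dose_max: float = 4.1
    # true biomarker response to dose intensity (per Gy/frac)
    ip10_dose_slope: float = 0.08
    zsv_dose_slope: float = -0.05
    biomarker_noise_sd: float = 0.05
    # logistic labeling parameters on week-6 gEUD (T<0: risk rises with dose)
    lc_mu: float = 45.0
    lc_t: float = -5.0
    rp2_mu: float = 32.0
    rp2_t: float = -5.0
    radbio: "_radbio.RadiobioParams" = field(default_factory=lambda: _radbio.RadiobioParams())

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not 0.0 <= self.genotype_allele_freq <= 1.0:
            raise ValueError("genotype_allele_freq must be in [0,1]")
        if self.ip10_log_sd <= 0 or self.zsv_log_sd <= 0:
            raise ValueError("log-normal sigmas must be positive")
        if self.tumor_geud_sd <= 0 or self.lung_geud_sd <= 0 or self.dose_sd <= 0:
            raise ValueError("normal sds must be positive")
        if not self.dose_min < self.dose_max:
            raise ValueError("dose_min must be < dose_max")
        if self.lc_t == 0 or self.rp2_t == 0:
            raise ValueError("logistic slopes must be nonzero")


@dataclass(frozen=True)
class GLSZMatrix:
    """Gray-level size-zone matrix: counts[i, j] = number of zones of
    gray level i (rows) and zone size j (columns, size = column index + 1)."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("GLSZM counts must be a 2-D matrix")
        if np.any(c < 0) or not np.all(np.isfinite(c)):
            raise ValueError("GLSZM counts must be finite and nonnegative")
        object.__setattr__(self, "counts", np.asarray(c, dtype=float))


def compute_zsv(matrix: GLSZMatrix | np.ndarray, variant: str = "variance") -> float:
    """Zone-size variance (ZSV) of a gray-level size-zone matrix.

    With ``variant="variance"`` (default) this is the variance of the zone
    size j under the normalized zone probabilities p(i, j) =
    counts(i, j) / sum(counts):

        ZSV = sum_{i,j} p(i,j) * (j - mu)^2,   mu = sum_{i,j} j * p(i,j)

    ``variant="printed"`` evaluates the literal textbook transcription
    (1/(N_g*L_z)) * sum_{i,j} (j*p(i,j) - mu)^2 instead; it is not a
    variance for non-uniform matrices and is kept only for comparison.
    """
    if not isinstance(matrix, GLSZMatrix):
        matrix = GLSZMatrix(np.asarray(matrix, dtype=float))
    c = matrix.counts
    total = c.sum()
    if total <= 0:
        raise ValueError("GLSZM must contain at least one nonzero zone count")
    p = c / total
    n_g, l_z = c.shape
    j = np.arange(1, l_z + 1, dtype=float)  # zone sizes along columns
    mu = float((p * j).sum())
    if variant == "variance":
        return float((p * (j - mu) ** 2).sum())
    if variant == "printed":
        return float(((j * p - mu) ** 2).sum() / (n_g * l_z))
    raise ValueError(f"unknown ZSV variant {variant!r}")


def _truncated_normal(rng, mean, sd, low, high, size):
    """Rejection-sampled truncated normal; deterministic given rng state."""
    out = np.empty(size)
    n = 0
    while n < size:
        draw = rng.normal(mean, sd, size=size)
        keep = draw[(draw >= low) & (draw <= high)]
        take = min(keep.size, size - n)
        out[n:n + take] = keep[:take]
        n += take
    return out


def generate_cohort(config: CohortConfig | None = None) -> list[PatientRecord]:
    """Generate a synthetic longitudinal NSCLC cohort.

    Deterministic given ``config.seed``.  The patient's dose intensity
    (``clinical_dose``) drives both the mid-treatment biomarker response
    and the outcome probabilities, giving the monotone dose-outcome
    relationship the self-evaluation scheme assumes.
    """
    config = config or CohortConfig()
    config.validate()
    rb = config.radbio
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    records: list[PatientRecord] = []
    if n == 0:
        return records

    ip10 = rng.lognormal(config.ip10_log_mean, config.ip10_log_sd, n)
    zsv = rng.lognormal(config.zsv_log_mean, config.zsv_log_sd, n)
    tg = _truncated_normal(rng, config.tumor_geud_mean, config.tumor_geud_sd, 5.0, 80.0, n)
    lg = _truncated_normal(rng, config.lung_geud_mean, config.lung_geud_sd, 1.0, 50.0, n)
    geno = rng.binomial(2, config.genotype_allele_freq, n)
    dose = np.clip(rng.normal(config.dose_mean, config.dose_sd, n),
                   config.dose_min, config.dose_max)

    # first two-thirds of the course = two adaptation periods
    dt_pre_mid = 2.0 * rb.dt_weeks
    noise = config.biomarker_noise_sd
    ip10_mid = ip10 * (1.0 + config.ip10_dose_slope * dose) * np.exp(rng.normal(0, noise, n))
    zsv_mid = zsv * np.clip(1.0 + config.zsv_dose_slope * dose, 0.1, None) \
        * np.exp(rng.normal(0, noise, n))
    tg_mid = np.array([
        _radbio.geud_transition(g, d, dt_pre_mid, rb, tissue="tumor")
        for g, d in zip(tg, dose)
    ])
    lg_mid = np.array([
        _radbio.geud_transition(g, d, dt_pre_mid, rb, tissue="lung")
        for g, d in zip(lg, dose)
    ])
    # week-6 gEUD after the adapted last third
    tg_6 = np.array([
        _radbio.geud_transition(g, d, rb.dt_weeks, rb, tissue="tumor")
        for g, d in zip(tg_mid, dose)
    ])
    lg_6 = np.array([
        _radbio.geud_transition(g, d, rb.dt_weeks, rb, tissue="lung")
        for g, d in zip(lg_mid, dose)
    ])
    p_lc = _radbio.outcome_probability(tg_6, _radbio.LogisticParams(config.lc_mu, config.lc_t))
    p_rp2 = _radbio.outcome_probability(lg_6, _radbio.LogisticParams(config.rp2_mu, config.rp2_t))
    lc = (rng.random(n) < p_lc).astype(int)
    rp2 = (rng.random(n) < p_rp2).astype(int)

    for i in range(n):
        pre = PatientState(ip10[i], zsv[i], tg[i], lg[i], int(geno[i]))
        mid = PatientState(ip10_mid[i], zsv_mid[i], tg_mid[i], lg_mid[i], int(geno[i]))
        records.append(PatientRecord(
            patient_id=f"P{i:04d}", state_pre=pre, state_mid=mid,
            clinical_dose=float(dose[i]), lc=int(lc[i]), rp2=int(rp2[i]),
        ))
    return records


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "patient_id": r.patient_id,
            "ip10_pre": r.state_pre.ip10,
            "zsv_pre": r.state_pre.glszm_zsv,
            "tumor_geud_pre": r.state_pre.tumor_geud,
            "lung_geud_pre": r.state_pre.lung_geud,
            "genotype": r.state_pre.cxcr1_genotype,
            "ip10_mid": r.state_mid.ip10,
            "zsv_mid": r.state_mid.glszm_zsv,
            "tumor_geud_mid": r.state_mid.tumor_geud,
            "lung_geud_mid": r.state_mid.lung_geud,
            "clinical_dose": r.clinical_dose,
            "lc": r.lc,
            "rp2": r.rp2,
        })
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file missing column(s): {missing}")
    records = []
    for idx, row in df.iterrows():
        lc, rp2 = row["lc"], row["rp2"]
        if lc not in (0, 1) or rp2 not in (0, 1):
            raise SchemaError(f"row {idx}: lc/rp2 must be binary, got lc={lc}, rp2={rp2}")
        if not row["clinical_dose"] > 0:
            raise SchemaError(f"row {idx}: clinical_dose must be positive")
        geno = int(row["genotype"])
        if geno not in (0, 1, 2):
            raise SchemaError(f"row {idx}: genotype must be 0, 1 or 2")
        try:
            pre = PatientState(row["ip10_pre"], row["zsv_pre"], row["tumor_geud_pre"],
                               row["lung_geud_pre"], geno)
            mid = PatientState(row["ip10_mid"], row["zsv_mid"], row["tumor_geud_mid"],
                               row["lung_geud_mid"], geno)
            records.append(PatientRecord(str(row["patient_id"]), pre, mid,
                                         float(row["clinical_dose"]), int(lc), int(rp2)))
        except ValueError as exc:
            raise SchemaError(f"row {idx}: {exc}") from exc
    return records


def write_cohort(records: list[PatientRecord], path) -> None:
    """Write records to the documented CSV schema (full float precision)."""
    records_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def read_cohort(path) -> list[PatientRecord]:
    """Read a cohort CSV, validating the schema row by row.

    Lines starting with ``#`` (provenance stamps) are ignored.
    """
    return frame_to_records(pd.read_csv(path, comment="#", float_precision="round_trip"))
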