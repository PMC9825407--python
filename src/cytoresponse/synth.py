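"""Synthetic mass cytometry cohort generator with known ground truth.

Emulates the structure of an induction-chemotherapy signaling study: a cohort
of leukemia patients sampled at 0 h (pre-treatment), 4 h and 24 h after the
start of therapy, multiplexed into batches that each carry an identical
reference aliquot and one healthy-donor sample, with

* ~10 immunophenotypic populations with distinct surface profiles,
* zero-inflated heavy-tailed raw intensities (Gaussian on the arcsinh scale,
  back-transformed with ``sinh`` and floored at zero),
* per-batch monotone channel distortions (affine on the transformed scale),
* treatment-induced functional-marker dynamics in the malignant/myeloid
  compartment (responders drop the target phospho-marker at 24 h,
  non-responders sustain or increase it), and
* survival times drawn from a proportional-hazards model on the patient's
  latent 24 h target-marker level.

All randomness flows from one integer seed through ``numpy.random.SeedSequence``
spawning; the splitting order (batch effects, patients, survival, clinical,
then one child stream per sample in manifest order) is fixed, so identical
spec + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    CLUSTERING_CHANNELS,
    EXCLUDED_CHANNELS,
    FUNCTIONAL_CHANNELS,
    CellTable,
    PanelConfig,
    ValidationError,
    default_panel,
)

#: Gaussian 90% quantile, used for the closed-form latent 90th percentile.
_Z90 = 1.2815515655446004


# ---------------------------------------------------------------------------
# Templates and model components
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationTemplate:
    """One immunophenotypic population.

    Means are on the arcsinh-transformed scale.  ``surface_means`` /
    ``functional_means`` list only the markers that deviate from the
    background level; unlisted channels sit at ``background``.

    ``response_weight`` scales how strongly the treatment-induced signaling
    dynamics act on this population (1 for the driving myeloid population,
    intermediate for other malignant populations, 0 for healthy lineages).
    Exactly one population per cohort has ``is_target=True``; its 24 h
    functional response is the latent value that drives survival.
    """

    name: str
    surface_means: dict
    functional_means: dict = field(default_factory=dict)
    background: float = 0.25
    functional_background: float = 1.2
    zero_inflation: float = 0.02
    dispersion: float = 0.35
    is_target: bool = False
    response_weight: float = 0.0

    def validate(self):
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValidationError(
                f"population {self.name}: zero_inflation must be in [0,1]"
            )
        if self.dispersion <= 0:
            raise ValidationError(f"population {self.name}: dispersion must be > 0")

    def mean_vector(self, channels) -> np.ndarray:
        out = np.empty(len(channels))
        for i, ch in enumerate(channels):
            if ch in self.surface_means:
                out[i] = self.surface_means[ch]
            elif ch in self.functional_means:
                out[i] = self.functional_means[ch]
            elif ch in FUNCTIONAL_CHANNELS:
                out[i] = self.functional_background
            else:
                out[i] = self.background
        return out


@dataclass(frozen=True)
class ResponseModel:
    """Treatment-induced dynamics of the functional (signaling) channels.

    The target marker in response-weighted populations moves by a patient
    level shift at 24 h: responders draw the shift around
    ``responder_shift_24h`` (negative, signaling shuts down), non-responders
    around ``nonresponder_shift_24h`` (non-negative, sustained/increased).
    ``baseline_sd`` is a persistent patient-level offset shared by all
    timepoints — it sets the within-patient correlation of signaling across
    timepoints, which is exposed as a parameter rather than asserted.
    ``comarker_weights`` lets correlated markers (e.g. p-p38) follow the same
    patient shift at a reduced weight.
    """

    target_marker: str = "p-ERK1/2"
    responder_fraction: float = 0.5
    responder_shift_24h: float = -1.2
    nonresponder_shift_24h: float = 0.5
    patient_sd: float = 0.35
    baseline_sd: float = 0.30
    shift_4h: float = 0.25
    comarker_weights: dict = field(default_factory=lambda: {"p-p38": 0.35})
    marker_noise_sd: float = 0.15
    timepoint_noise_sd: float = 0.15  # per patient x marker x timepoint jitter

    def validate(self):
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValidationError("responder_fraction must be in [0,1]")
        if self.responder_shift_24h > 0:
            raise ValidationError("responder_shift_24h must be <= 0")
        if self.nonresponder_shift_24h < 0:
            raise ValidationError("nonresponder_shift_24h must be >= 0")
        if self.patient_sd < 0 or self.baseline_sd < 0:
            raise ValidationError("response noise s.d. must be >= 0")


@dataclass(frozen=True)
class SurvivalModel:
    """Proportional-hazards generator for overall survival.

    Event times are exponential with rate ``baseline_hazard * exp(beta * z)``
    where ``z`` is the cohort-standardized latent 24 h target value; ``beta``
    is therefore a log hazard ratio per standard deviation.  Follow-up is
    administratively censored at ``censor_horizon_days``.
    """

    baseline_hazard: float = np.log(2) / 600.0  # median ~600 days at z = 0
    beta: float = 1.0
    censor_horizon_days: float = 1826.0  # five years

    def validate(self):
        if self.baseline_hazard <= 0:
            raise ValidationError("baseline_hazard must be > 0")
        if self.censor_horizon_days < 0:
            raise ValidationError("censor_horizon_days must be >= 0")


def default_populations() -> tuple:
    """Ten populations spanning the major blood lineages plus malignant ones.

    Phenotypes follow the usual marker conventions: CD34+CD117+ blasts, a
    large dim-myeloid population carrying the treatment response (the
    counterpart of the heterogeneous myeloid metacluster), granulocytes
    (CD66b high, CD45 low), T/B/NK lymphocytes (CD45 high), CD14+ monocytes
    and CD34+CD90+ stem cells.
    """
    hi, mid, dim = 4.0, 3.0, 1.5
    return (
        PopulationTemplate(
            "cd34_blast",
            {"CD34": hi, "CD117": 3.5, "CD38": 2.5, "CD33": 2.0, "HLA-DR": dim,
             "CD45": 1.2, "CD123": 1.0},
            response_weight=0.15,
        ),
        PopulationTemplate(
            "cd34_cd123_blast",
            {"CD34": 3.5, "CD117": 1.0, "HLA-DR": 3.5, "CD33": 3.5, "CD123": hi,
             "CD45": 1.2, "CD38": 2.5},
            response_weight=0.15,
        ),
        PopulationTemplate(
            "granulocytes",
            {"CD66b": 4.5, "CD16": 3.5, "CD11b": mid, "CD45": dim, "CD33": dim},
        ),
        PopulationTemplate(
            "t_cd4",
            {"CD3": hi, "CD4": hi, "CD45": 4.5, "CD7": mid},
        ),
        PopulationTemplate(
            "t_cd8",
            {"CD3": hi, "CD8a": hi, "CD45": 4.5, "CD7": mid},
        ),
        PopulationTemplate(
            "b_cells",
            {"CD20": hi, "HLA-DR": 3.5, "CD45": hi},
        ),
        PopulationTemplate(
            "nk_cells",
            {"CD56": hi, "CD16": mid, "CD7": 3.5, "CD45": hi},
        ),
        PopulationTemplate(
            "monocytes",
            {"CD14": 4.5, "CD33": 3.5, "CD64": 3.5, "HLA-DR": mid, "CD11b": 3.5,
             "CD45": 3.5, "CD4": dim},
        ),
        PopulationTemplate(
            "myeloid_target",
            {"CD64": dim, "CD33": dim, "HLA-DR": 1.2, "CD45": dim, "CD34": 0.8,
             "CD66b": 0.5},
            functional_means={"p-ERK1/2": 1.5},
            is_target=True,
            response_weight=1.0,
        ),
        PopulationTemplate(
            "hsc",
            {"CD34": hi, "CD90": mid, "CD45": dim, "CD38": 1.0},
            response_weight=0.15,
        ),
    )


#: Mean composition of the shared healthy reference material (pooled blood):
#: ~60% granulocytes, ~30% lymphocytes, ~3% monocytes.
HEALTHY_COMPOSITION = {
    "granulocytes": 0.60,
    "t_cd4": 0.12,
    "t_cd8": 0.08,
    "b_cells": 0.05,
    "nk_cells": 0.05,
    "monocytes": 0.03,
    "myeloid_target": 0.05,
    "cd34_blast": 0.005,
    "cd34_cd123_blast": 0.005,
    "hsc": 0.01,
}

#: Mean composition of patient samples: expanded blast/myeloid compartment.
PATIENT_COMPOSITION = {
    "cd34_blast": 0.15,
    "cd34_cd123_blast": 0.03,
    "granulocytes": 0.18,
    "t_cd4": 0.07,
    "t_cd8": 0.05,
    "b_cells": 0.03,
    "nk_cells": 0.03,
    "monocytes": 0.03,
    "myeloid_target": 0.40,
    "hsc": 0.03,
}


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort.

    ``patient_composition``/``healthy_composition`` are mean population
    fractions; per-patient (per-donor) compositions are Dirichlet draws with
    concentration ``patient_dirichlet`` (``healthy_dirichlet``), i.e. the
    Dirichlet alpha for population *p* is ``composition[p] * concentration``.
    Batch reference aliquots are drawn from the healthy mean composition
    itself (one shared distribution) before the per-batch distortion.

    Batch distortions are affine maps ``v -> a*v + b`` on the transformed
    scale with slopes in ``batch_slope_range`` (must stay positive: the
    distortions are monotone) and offsets in ``batch_offset_range``
    (non-negative by default so that raw intensities stay non-negative).
    """

    n_patients: int = 32
    timepoints: tuple = (0.0, 4.0, 24.0)
    n_batches: int = 7
    populations: tuple = field(default_factory=default_populations)
    patient_composition: dict = field(default_factory=lambda: dict(PATIENT_COMPOSITION))
    healthy_composition: dict = field(default_factory=lambda: dict(HEALTHY_COMPOSITION))
    patient_dirichlet: float = 30.0
    healthy_dirichlet: float = 200.0
    batch_effects: dict | None = None  # batch_id -> channel -> (a, b); None = drawn
    batch_slope_range: tuple = (0.85, 1.25)
    batch_offset_range: tuple = (0.0, 0.45)
    response: ResponseModel = field(default_factory=ResponseModel)
    survival: SurvivalModel = field(default_factory=SurvivalModel)
    cells_per_sample: int = 1000
    #: reference aliquots are acquired as full samples, so they carry many
    #: more events than the per-sample analysis subsets; small references
    #: make the 101-quantile map's mode boundaries noisy
    reference_cells: int | None = 5000
    n_drop_4h: int = 0  # patients generated without a 4 h sample
    seed: int = 0

    def validate(self):
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if self.n_batches < 1:
            raise ValidationError("n_batches must be >= 1")
        if 0.0 not in [float(t) for t in self.timepoints] or 24.0 not in [
            float(t) for t in self.timepoints
        ]:
            raise ValidationError("timepoints must include 0 and 24 h")
        if self.cells_per_sample < 100:
            raise ValidationError("cells_per_sample must be >= 100")
        targets = [p.name for p in self.populations if p.is_target]
        if len(targets) != 1:
            raise ValidationError(
                f"exactly one population must have is_target=True, got {targets}"
            )
        for p in self.populations:
            p.validate()
        for comp_name, comp in (
            ("patient_composition", self.patient_composition),
            ("healthy_composition", self.healthy_composition),
        ):
            for name, frac in comp.items():
                if frac <= 0:
                    raise ValidationError(f"{comp_name}[{name}] must be > 0")
            known = {p.name for p in self.populations}
            unknown = set(comp) - known
            if unknown:
                raise ValidationError(f"{comp_name} names unknown populations: {unknown}")
        if self.patient_dirichlet <= 0 or self.healthy_dirichlet <= 0:
            raise ValidationError("Dirichlet concentrations must be > 0")
        if self.batch_slope_range[0] <= 0:
            raise ValidationError("batch effect slopes must be > 0 (monotone)")
        if self.n_drop_4h < 0 or self.n_drop_4h > self.n_patients:
            raise ValidationError("n_drop_4h must be in [0, n_patients]")
        self.response.validate()
        self.survival.validate()

    @property
    def panel(self) -> PanelConfig:
        return default_panel()

    @property
    def target_population(self) -> str:
        return next(p.name for p in self.populations if p.is_target)

    @property
    def n_reference_cells(self) -> int:
        return self.reference_cells if self.reference_cells is not None else self.cells_per_sample


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    cell_labels: dict            # sample_id -> array of population names
    patients: pd.DataFrame       # patient-level latents and survival record
    batch_params: dict           # batch_id -> channel -> (a, b)
    beta: float
    target_population: str
    target_marker: str
    populations: tuple


@dataclass
class SyntheticCohort:
    samples: dict                # sample_id -> CellTable (raw scale, distorted)
    manifest: pd.DataFrame
    clinical: pd.DataFrame
    truth: GroundTruth
    spec: CohortSpec

    def tables(self, role=None, timepoint_h=None):
        out = []
        for sid in self.manifest["sample_id"]:
            t = self.samples[sid]
            if role is not None and t.sample_role != role:
                continue
            if timepoint_h is not None and t.timepoint_h != timepoint_h:
                continue
            out.append(t)
        return out

    def references(self) -> dict:
        """Batch reference aliquots keyed by batch_id."""
        return {t.batch_id: t for t in self.tables(role="batch_reference")}


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def apply_batch_effect(table: CellTable, params: dict, cofactor: float = 5.0) -> CellTable:
    """Distort a raw-scale sample with per-channel affine maps on the
    transformed scale: ``x -> c*sinh(a*asinh(x/c) + b)``.

    Slopes must be positive so the distortion is monotone and within-channel
    cell ranking is preserved.  Channels absent from ``params`` pass through.
    """
    for ch, (a, _b) in params.items():
        if a <= 0:
            raise ValidationError(f"batch effect slope for {ch} must be > 0, got {a}")
    df = table.data.copy()
    for ch, (a, b) in params.items():
        if ch not in df.columns:
            continue
        v = np.arcsinh(df[ch].to_numpy(dtype=float) / cofactor)
        df[ch] = np.maximum(cofactor * np.sinh(a * v + b), 0.0)
    return table.with_data(df)


def _draw_batch_params(spec: CohortSpec, rng: np.random.Generator) -> dict:
    channels = spec.panel.all_channels
    lo_a, hi_a = spec.batch_slope_range
    lo_b, hi_b = spec.batch_offset_range
    out = {}
    for b in range(1, spec.n_batches + 1):
        out[f"B{b}"] = {
            ch: (float(rng.uniform(lo_a, hi_a)), float(rng.uniform(lo_b, hi_b)))
            for ch in channels
        }
    return out


def simulate_patients(spec: CohortSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw patient-level latents: responder status, persistent baseline
    offset, 24 h shift, and the latent 24 h 90th percentile of the target
    marker in the target population (closed-form Gaussian quantile).
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[1])
    resp = spec.response
    target = next(p for p in spec.populations if p.is_target)
    n = spec.n_patients
    responder = rng.random(n) < resp.responder_fraction
    baseline_offset = rng.normal(0.0, resp.baseline_sd, size=n)
    noise = rng.normal(0.0, resp.patient_sd, size=n)
    shift24 = np.where(
        responder, resp.responder_shift_24h, resp.nonresponder_shift_24h
    ) + noise
    # measurement-level jitter of the target marker per timepoint (sample
    # handling / staining variation); the realized 24 h jitter is part of
    # the latent value the survival model acts on
    tp_noise = rng.normal(
        0.0, resp.timepoint_noise_sd, size=(n, len(spec.timepoints))
    )
    tp_index = {float(t): j for j, t in enumerate(spec.timepoints)}
    base_mean = target.functional_means.get(
        resp.target_marker, target.functional_background
    )
    latent = (
        base_mean + baseline_offset + shift24 + tp_noise[:, tp_index[24.0]]
        + _Z90 * target.dispersion
    )
    sd = latent.std(ddof=0)
    z = (latent - latent.mean()) / sd if sd > 0 else np.zeros(n)
    out = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:02d}" for i in range(n)],
            "responder": responder,
            "baseline_offset": baseline_offset,
            "shift24": shift24,
            "latent_p90_24h": latent,
            "z": z,
        }
    )
    for tp, j in tp_index.items():
        out[f"target_tp_noise_{tp:g}h"] = tp_noise[:, j]
    return out


def simulate_survival(
    latent: np.ndarray,
    model: SurvivalModel,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Exponential proportional-hazards survival from standardized latents.

    Event time ~ Exp(rate = h0 * exp(beta * z)); observed time is capped at
    the censoring horizon, with the event flag set accordingly.
    """
    model.validate()
    latent = np.asarray(latent, dtype=float)
    if not np.all(np.isfinite(latent)):
        raise ValidationError("latent values must be finite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = latent.std(ddof=0)
    z = (latent - latent.mean()) / sd if sd > 0 else np.zeros_like(latent)
    rate = model.baseline_hazard * np.exp(model.beta * z)
    event_time = rng.exponential(1.0 / rate)
    horizon = model.censor_horizon_days
    if horizon == 0:
        warnings.warn("censor horizon is 0: degenerate cohort, all records censored at 0")
    os_days = np.minimum(event_time, horizon)
    os_event = (event_time <= horizon).astype(int)
    if horizon == 0:
        os_event[:] = 0
    return pd.DataFrame(
        {
            "z": z,
            "event_time": event_time,
            "censor_time": np.full_like(event_time, horizon),
            "os_days": os_days,
            "os_event": os_event,
        }
    )


# ---------------------------------------------------------------------------
# Cell-level generation
# ---------------------------------------------------------------------------

def _draw_cells(
    spec: CohortSpec,
    composition: np.ndarray,
    n_cells: int,
    rng: np.random.Generator,
    functional_shift=None,
):
    """Draw one sample's raw-scale cell matrix plus population labels.

    ``functional_shift`` maps marker name -> per-population additive shift
    array (on the transformed scale), already weighted by response_weight.
    """
    pops = spec.populations
    channels = spec.panel.all_channels
    cofactor = spec.panel.cofactor
    counts = rng.multinomial(n_cells, composition)
    blocks, labels = [], []
    for p, cnt in zip(pops, counts):
        if cnt == 0:
            continue
        mu = p.mean_vector(channels)
        v = rng.normal(0.0, 1.0, size=(cnt, len(channels))) * p.dispersion + mu
        if functional_shift:
            for marker, shifts in functional_shift.items():
                j = channels.index(marker)
                v[:, j] += shifts[p.name]
        if p.zero_inflation > 0:
            # dropout is intensity-dependent: bright channels essentially
            # never read an exact zero, dim channels often do
            zi = np.where(mu < 1.5, p.zero_inflation, p.zero_inflation * 0.1)
            zero = rng.random((cnt, len(channels))) < zi
            v[zero] = 0.0
        raw = np.maximum(cofactor * np.sinh(v), 0.0)
        blocks.append(raw)
        labels.extend([p.name] * cnt)
    data = pd.DataFrame(np.vstack(blocks), columns=list(channels))
    return data, np.array(labels)


def _functional_shifts(spec, timepoint_h, baseline_offset, shift24, marker_noise):
    """Per-marker, per-population transformed-scale shifts for one sample.

    ``marker_noise`` maps marker -> additive offset for this patient at this
    timepoint (persistent patient-marker offset plus timepoint jitter).
    """
    resp = spec.response
    if timepoint_h == 0:
        tshift = 0.0
    elif timepoint_h == 24:
        tshift = shift24
    else:
        tshift = resp.shift_4h
    weights = {resp.target_marker: 1.0, **resp.comarker_weights}
    out = {}
    for marker, w in weights.items():
        out[marker] = {
            p.name: p.response_weight * w * (baseline_offset + tshift)
            + marker_noise.get(marker, 0.0)
            for p in spec.populations
        }
    return out


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate the full cohort: one cell table per patient x timepoint, one
    reference aliquot and one healthy donor per batch, a manifest, a clinical
    table, and the ground truth.
    """
    spec.validate()
    panel = spec.panel
    ss = np.random.SeedSequence(spec.seed)
    ss_batch, ss_patients, ss_survival, ss_clinical, ss_cells = ss.spawn(5)

    batch_params = (
        spec.batch_effects
        if spec.batch_effects is not None
        else _draw_batch_params(spec, np.random.default_rng(ss_batch))
    )
    batch_ids = sorted(batch_params)
    if len(batch_ids) != spec.n_batches:
        raise ValidationError(
            f"batch_effects must define {spec.n_batches} batches, got {len(batch_ids)}"
        )

    rng_pat = np.random.default_rng(ss_patients)
    patients = simulate_patients(spec, rng_pat)
    # per-patient composition and per-patient-marker idiosyncratic offsets
    pop_names = [p.name for p in spec.populations]
    pat_alpha = np.array(
        [spec.patient_composition.get(n, 1e-6) * spec.patient_dirichlet for n in pop_names]
    )
    compositions = rng_pat.dirichlet(pat_alpha, size=spec.n_patients)
    resp = spec.response
    noise_markers = [resp.target_marker, *resp.comarker_weights]
    marker_noise = rng_pat.normal(
        0.0, resp.marker_noise_sd, size=(spec.n_patients, len(noise_markers))
    )
    marker_noise[:, 0] = 0.0  # target marker: latent is defined without a
    # persistent offset; its per-timepoint jitter comes from simulate_patients
    comarkers = list(resp.comarker_weights)
    tps = [float(t) for t in spec.timepoints]
    co_tp_noise = rng_pat.normal(
        0.0, resp.timepoint_noise_sd,
        size=(spec.n_patients, len(comarkers), len(tps)),
    )

    surv = simulate_survival(
        patients["latent_p90_24h"].to_numpy(),
        spec.survival,
        np.random.default_rng(ss_survival),
    )
    patients = pd.concat([patients, surv.drop(columns="z")], axis=1)

    rng_clin = np.random.default_rng(ss_clinical)
    age = np.clip(np.round(rng_clin.normal(52, 10, spec.n_patients)), 20, 78).astype(int)
    sex = np.where(rng_clin.random(spec.n_patients) < 0.5, "F", "M")
    cr_p = np.where(patients["responder"], 0.8, 0.4)
    cr_status = np.where(rng_clin.random(spec.n_patients) < cr_p, "CR", "nonCR")
    tx_draw = rng_clin.random(spec.n_patients) < 0.3
    tx_day = np.round(rng_clin.uniform(90, 250, spec.n_patients))
    transplant_day = np.where(
        tx_draw & (tx_day < patients["os_days"].to_numpy()), tx_day, np.nan
    )
    clinical = pd.DataFrame(
        {
            "patient_id": patients["patient_id"],
            "age": age,
            "sex": sex,
            "os_days": patients["os_days"].round(2),
            "os_event": patients["os_event"],
            "transplant_day": transplant_day,
            "cr_status": cr_status,
        }
    )

    # ---- manifest layout (deterministic order) -----------------------------
    drop_4h = set(patients["patient_id"].iloc[: spec.n_drop_4h])
    rows = []
    for i, pid in enumerate(patients["patient_id"]):
        batch = batch_ids[i % spec.n_batches]
        for tp in spec.timepoints:
            tp = float(tp)
            if tp == 4.0 and pid in drop_4h:
                continue
            rows.append((f"{pid}_T{tp:g}", pid, tp, batch, "patient"))
    for b in batch_ids:
        rows.append((f"REF_{b}", None, np.nan, b, "batch_reference"))
    for b in batch_ids:
        rows.append((f"HD_{b}", None, np.nan, b, "healthy_donor"))
    manifest = pd.DataFrame(
        rows, columns=["sample_id", "patient_id", "timepoint_h", "batch_id", "sample_role"]
    )

    healthy_base = np.array([spec.healthy_composition.get(n, 1e-6) for n in pop_names])
    healthy_base = healthy_base / healthy_base.sum()
    healthy_alpha = healthy_base * spec.healthy_dirichlet

    pid_to_ix = {pid: i for i, pid in enumerate(patients["patient_id"])}
    samples, cell_labels = {}, {}
    sample_seeds = ss_cells.spawn(len(manifest))
    for (row, sseed) in zip(manifest.itertuples(index=False), sample_seeds):
        rng = np.random.default_rng(sseed)
        if row.sample_role == "patient":
            i = pid_to_ix[row.patient_id]
            tp = float(row.timepoint_h)
            tpi = tps.index(tp)
            noise = {
                resp.target_marker: float(
                    patients[f"target_tp_noise_{tp:g}h"].iloc[i]
                )
            }
            for j, m in enumerate(comarkers):
                noise[m] = float(marker_noise[i, j + 1] + co_tp_noise[i, j, tpi])
            shifts = _functional_shifts(
                spec,
                tp,
                patients["baseline_offset"].iloc[i],
                patients["shift24"].iloc[i],
                noise,
            )
            data, labels = _draw_cells(
                spec, compositions[i], spec.cells_per_sample, rng, shifts
            )
        elif row.sample_role == "batch_reference":
            data, labels = _draw_cells(spec, healthy_base, spec.n_reference_cells, rng)
        else:  # healthy_donor
            comp = rng.dirichlet(healthy_alpha)
            data, labels = _draw_cells(spec, comp, spec.cells_per_sample, rng)
        table = CellTable(
            sample_id=row.sample_id,
            data=data,
            scale="raw",
            patient_id=row.patient_id,
            timepoint_h=None if np.isnan(row.timepoint_h) else float(row.timepoint_h),
            batch_id=row.batch_id,
            sample_role=row.sample_role,
        )
        samples[row.sample_id] = apply_batch_effect(
            table, batch_params[row.batch_id], panel.cofactor
        )
        cell_labels[row.sample_id] = labels

    truth = GroundTruth(
        cell_labels=cell_labels,
        patients=patients,
        batch_params=batch_params,
        beta=spec.survival.beta,
        target_population=spec.target_population,
        target_marker=spec.response.target_marker,
        populations=spec.populations,
    )
    return SyntheticCohort(
        samples=samples, manifest=manifest, clinical=clinical, truth=truth, spec=spec
    )
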