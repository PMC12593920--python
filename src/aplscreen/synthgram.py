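"""Synthetic cohort generator for hematology-analyzer scattergram screening.

Each simulated patient sample carries two 3-D event clouds — one for the
DIFF channel (leukocyte differential) and one for the WNB channel
(WBC/NRBC/basophil chemistry) — plus a 50-column table of routine blood
parameters (CBC counts and cell-population-data summaries).  Events live in
an abstract unit cube with axes (FS, SS, FL): forward scatter ~ cell size,
side scatter ~ granularity, fluorescence ~ nucleic-acid content.

The four study classes are APL (acute promyelocytic leukemia, the positive
class), AML (other acute myeloid leukemias), ALL (acute lymphoblastic
leukemia) and HC (healthy controls).  APL samples carry an extra abnormal
promyelocyte population — a high-fluorescence, large-volume cluster in the
WNB channel and an atypical granulocyte cluster in DIFF.  AML and ALL carry
their own blast clusters that partially overlap the APL cluster, and all
three leukemia classes share depressed platelet indices, so that only the
morphological signature is APL-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

DIFF = "DIFF"
WNB = "WNB"
CHANNELS = (DIFF, WNB)
CLASS_NAMES = ("APL", "AML", "ALL", "HC")

#: population labels the generator understands
POPULATION_NAMES = (
    "Neu", "Lym", "Mon", "Eos", "Debris", "AbnPromyelocyte", "Blast", "Lymphoblast",
)


class ConfigurationError(ValueError):
    """Raised for unknown class/population names or missing spec entries."""


class ValidationError(ValueError):
    """Raised when a spec violates its invariants (e.g. non-PSD covariance)."""


@dataclass(frozen=True)
class PopulationSpec:
    """One Gaussian cell population inside a channel's event cloud.

    ``mean`` is the (FS, SS, FL) center in the unit cube, ``cov`` the 3x3
    covariance, ``fraction`` the expected share of events in the cloud.
    """

    name: str
    channel: str
    mean: tuple[float, float, float]
    cov: np.ndarray
    fraction: float

    def __post_init__(self) -> None:
        if self.name not in POPULATION_NAMES:
            raise ConfigurationError(f"unknown population name {self.name!r}")
        if self.channel not in CHANNELS:
            raise ConfigurationError(f"unknown channel {self.channel!r}")
        cov = np.asarray(self.cov, dtype=float)
        if cov.shape != (3, 3):
            raise ValidationError("covariance must be 3x3")
        if not np.allclose(cov, cov.T, atol=1e-12):
            raise ValidationError("covariance must be symmetric")
        if np.linalg.eigvalsh(cov).min() < -1e-10:
            raise ValidationError("covariance must be positive semi-definite")
        m = np.asarray(self.mean, dtype=float)
        if m.shape != (3,) or (m < 0).any() or (m >= 1).any():
            raise ValidationError("population mean must lie in the unit cube")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValidationError("fraction must be in [0, 1]")
        object.__setattr__(self, "cov", cov)


@dataclass(frozen=True)
class ClassSpec:
    """Full generative description of one study class.

    ``n_events_scale`` multiplies the nominal per-cloud event count so a
    class with an extra abnormal population keeps the same absolute
    concentration of the common populations.
    """

    class_name: str
    populations: tuple[PopulationSpec, ...]
    routine_param_dists: dict[str, tuple[float, float, float, float]]
    n_events_scale: float = 1.0
    #: per-sample abnormal-cell burden (uniform draw) replacing the nominal
    #: abnormal fraction; None = fixed mixture
    abn_fraction_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.class_name not in CLASS_NAMES:
            raise ConfigurationError(f"unknown class name {self.class_name!r}")
        for channel in CHANNELS:
            frac = sum(p.fraction for p in self.populations if p.channel == channel)
            if abs(frac - 1.0) > 1e-9:
                raise ValidationError(
                    f"{self.class_name}/{channel}: population fractions sum to "
                    f"{frac}, expected 1"
                )
        for name, (mu, sd, lo, hi) in self.routine_param_dists.items():
            if sd < 0:
                raise ValidationError(f"{name}: sd must be >= 0")
            if lo > hi:
                raise ValidationError(f"{name}: clip bounds out of order")

    def channel_populations(self, channel: str) -> tuple[PopulationSpec, ...]:
        return tuple(p for p in self.populations if p.channel == channel)


@dataclass
class EventCloud:
    """Simulated events for one sample and one channel."""

    channel: str
    fs: np.ndarray
    ss: np.ndarray
    fl: np.ndarray
    population: np.ndarray  # array of str labels, parallel to the coordinates
    sample_id: str = ""

    @property
    def n_events(self) -> int:
        return self.fs.size


@dataclass
class CohortSample:
    sample_id: str
    class_name: str
    diff_cloud: EventCloud
    wnb_cloud: EventCloud
    routine_params: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# 50-parameter routine roster (CBC + cell population data).  The width is a
# hard contract; the membership keeps every parameter referenced by the
# screening literature (PLT, PCT, WBC, MCV, MCHC, D-Neu-SFL-W, leukocyte
# counts and ratios) and fills the remainder with standard CBC/CPD names.
ROUTINE_PARAM_NAMES: tuple[str, ...] = (
    "WBC", "RBC", "HGB", "HCT", "MCV", "MCH", "MCHC", "RDW-CV", "RDW-SD",
    "PLT", "PCT", "MPV", "PDW", "P-LCR", "P-LCC",
    "NEUT#", "NEUT%", "LYMPH#", "LYMPH%", "MONO#", "MONO%",
    "EO#", "EO%", "BASO#", "BASO%", "IG#", "IG%", "NRBC#", "NRBC%",
    "RET#", "RET%", "IRF", "RET-He",
    "D-Neu-SFL-P", "D-Neu-SFL-W", "D-Neu-SSC-P", "D-Neu-SSC-W",
    "D-Lym-SFL-P", "D-Lym-SFL-W", "D-Lym-SSC-P", "D-Lym-SSC-W",
    "D-Mon-SFL-P", "D-Mon-SFL-W", "D-Mon-SSC-P", "D-Mon-SSC-W",
    "N-WBC-SFL-P", "N-WBC-SFL-W", "N-WBC-FSC-P", "N-WBC-FSC-W", "N-BAS-SSC-P",
)

assert len(ROUTINE_PARAM_NAMES) == 50


def _diag(sx: float, sy: float, sz: float) -> np.ndarray:
    return np.diag([sx**2, sy**2, sz**2])


def _pop(name, channel, mean, sd, fraction) -> PopulationSpec:
    return PopulationSpec(name, channel, mean, _diag(*sd), fraction)


# Healthy leukocyte cluster geometry, shared across classes (axes FS, SS, FL).
_DIFF_BASE = {
    "Debris": ((0.12, 0.08, 0.05), (0.04, 0.03, 0.02)),
    "Lym": ((0.32, 0.18, 0.30), (0.04, 0.03, 0.04)),
    "Mon": ((0.50, 0.34, 0.52), (0.04, 0.04, 0.04)),
    "Neu": ((0.55, 0.60, 0.33), (0.05, 0.05, 0.04)),
    "Eos": ((0.58, 0.80, 0.46), (0.03, 0.03, 0.03)),
}
_WNB_BASE = {
    "Debris": ((0.10, 0.10, 0.06), (0.03, 0.03, 0.02)),
    "Lym": ((0.30, 0.22, 0.26), (0.04, 0.03, 0.04)),
    "Mon": ((0.46, 0.36, 0.44), (0.04, 0.04, 0.04)),
    "Neu": ((0.52, 0.58, 0.30), (0.05, 0.05, 0.04)),
}

# Abnormal clusters.  The APL promyelocyte population is a *dense, compact*
# high-fluorescence large-volume cluster (tight covariance), well separated
# in WNB; AML blasts and ALL lymphoblasts are deliberately diffuse clouds at
# partially overlapping positions, so the APL signature is distinctive both
# by location and by local appearance.
_ABN = {
    "APL": {
        DIFF: _pop("AbnPromyelocyte", DIFF, (0.62, 0.70, 0.68), (0.04, 0.04, 0.04), 0.0),
        WNB: _pop("AbnPromyelocyte", WNB, (0.78, 0.55, 0.84), (0.03, 0.03, 0.03), 0.0),
    },
    # AML blasts share the APL cluster's (SS, FL) footprint in WNB but have
    # ordinary forward scatter, so only the FS-FL perspective resolves the
    # two; in DIFF they overlap the promyelocyte region partially.
    "AML": {
        DIFF: _pop("Blast", DIFF, (0.55, 0.62, 0.62), (0.07, 0.07, 0.07), 0.0),
        WNB: _pop("Blast", WNB, (0.45, 0.52, 0.78), (0.08, 0.08, 0.08), 0.0),
    },
    "ALL": {
        DIFF: _pop("Lymphoblast", DIFF, (0.38, 0.22, 0.52), (0.08, 0.07, 0.09), 0.0),
        WNB: _pop("Lymphoblast", WNB, (0.36, 0.26, 0.50), (0.08, 0.07, 0.09), 0.0),
    },
}

# Healthy mixture per channel.  Disease classes keep the same *absolute*
# concentration of these common populations and add their abnormal cluster
# on top: the common fractions are scaled by (1 - abnormal fraction) and
# the per-class event count is scaled up by 1/(1 - abnormal fraction), so
# the planted cluster — not a compositional shift of normal populations —
# is the image-level class signal (routine parameters carry the
# differential shifts instead).
_HC_FRACTIONS = {
    DIFF: {"Debris": 0.05, "Lym": 0.30, "Mon": 0.08, "Neu": 0.54, "Eos": 0.03},
    WNB: {"Debris": 0.06, "Lym": 0.32, "Mon": 0.08, "Neu": 0.54},
}

#: nominal abnormal-population fraction per disease class (both channels)
_ABN_FRACTION = {"APL": 0.35, "AML": 0.35, "ALL": 0.35, "HC": 0.0}

#: per-sample abnormal-cell burden range (uniform draw); disease severity
#: varies between patients, which keeps every scattergram feature noisy
_ABN_RANGE = {"APL": (0.10, 0.40), "AML": (0.10, 0.45), "ALL": (0.10, 0.45),
              "HC": None}


def _class_fractions(class_name: str) -> dict[str, dict[str, float]]:
    abn = _ABN_FRACTION[class_name]
    out = {}
    for channel, base in _HC_FRACTIONS.items():
        fr = {name: f * (1.0 - abn) for name, f in base.items()}
        if abn > 0:
            fr[_ABN[class_name][channel].name] = abn
        out[channel] = fr
    return out

# Routine-parameter distributions: (mean, sd, clip lo, clip hi).  HC centers
# are textbook reference values; all three leukemia classes share cytopenias
# (low PLT/PCT, shifted differentials) so routine parameters alone do not
# isolate APL.  Units follow common CBC reporting (counts x10^9/L, HGB g/L).
_ROUTINE_HC = {
    "WBC": (6.5, 1.6, 1.5, 20.0), "RBC": (4.7, 0.4, 2.0, 6.5),
    "HGB": (140.0, 12.0, 60.0, 180.0), "HCT": (0.42, 0.035, 0.15, 0.60),
    "MCV": (90.0, 4.5, 60.0, 120.0), "MCH": (30.0, 1.8, 18.0, 40.0),
    "MCHC": (335.0, 10.0, 280.0, 380.0), "RDW-CV": (13.0, 0.9, 10.0, 30.0),
    "RDW-SD": (42.0, 3.0, 30.0, 80.0),
    "PLT": (250.0, 55.0, 5.0, 600.0), "PCT": (0.25, 0.05, 0.01, 0.60),
    "MPV": (10.2, 0.9, 6.0, 15.0), "PDW": (12.5, 1.8, 8.0, 25.0),
    "P-LCR": (26.0, 5.0, 5.0, 60.0), "P-LCC": (65.0, 15.0, 5.0, 150.0),
    "NEUT#": (3.8, 1.0, 0.1, 15.0), "NEUT%": (58.0, 7.0, 5.0, 95.0),
    "LYMPH#": (2.0, 0.5, 0.1, 10.0), "LYMPH%": (31.0, 6.0, 2.0, 90.0),
    "MONO#": (0.5, 0.15, 0.0, 3.0), "MONO%": (7.0, 1.8, 0.0, 40.0),
    "EO#": (0.18, 0.08, 0.0, 2.0), "EO%": (2.8, 1.2, 0.0, 20.0),
    "BASO#": (0.04, 0.02, 0.0, 0.5), "BASO%": (0.6, 0.3, 0.0, 5.0),
    "IG#": (0.02, 0.015, 0.0, 5.0), "IG%": (0.3, 0.2, 0.0, 40.0),
    "NRBC#": (0.0, 0.005, 0.0, 2.0), "NRBC%": (0.0, 0.05, 0.0, 20.0),
    "RET#": (55.0, 12.0, 5.0, 300.0), "RET%": (1.2, 0.3, 0.1, 8.0),
    "IRF": (8.0, 2.5, 1.0, 50.0), "RET-He": (32.0, 2.0, 15.0, 45.0),
    "D-Neu-SFL-P": (88.0, 6.0, 40.0, 200.0), "D-Neu-SFL-W": (62.0, 6.0, 20.0, 250.0),
    "D-Neu-SSC-P": (152.0, 6.0, 80.0, 250.0), "D-Neu-SSC-W": (60.0, 6.0, 20.0, 200.0),
    "D-Lym-SFL-P": (70.0, 5.0, 30.0, 180.0), "D-Lym-SFL-W": (55.0, 5.0, 20.0, 200.0),
    "D-Lym-SSC-P": (78.0, 5.0, 40.0, 160.0), "D-Lym-SSC-W": (42.0, 5.0, 15.0, 150.0),
    "D-Mon-SFL-P": (118.0, 6.0, 60.0, 220.0), "D-Mon-SFL-W": (58.0, 6.0, 20.0, 200.0),
    "D-Mon-SSC-P": (98.0, 5.0, 50.0, 180.0), "D-Mon-SSC-W": (48.0, 5.0, 15.0, 150.0),
    "N-WBC-SFL-P": (82.0, 6.0, 40.0, 220.0), "N-WBC-SFL-W": (58.0, 6.0, 20.0, 250.0),
    "N-WBC-FSC-P": (120.0, 7.0, 60.0, 240.0), "N-WBC-FSC-W": (55.0, 6.0, 20.0, 200.0),
    "N-BAS-SSC-P": (70.0, 5.0, 30.0, 150.0),
}

# Per-class overrides (everything not listed falls back to the HC values).
_ROUTINE_OVERRIDES = {
    "APL": {
        "WBC": (8.0, 6.0, 0.5, 60.0), "PLT": (60.0, 35.0, 5.0, 300.0),
        "PCT": (0.07, 0.035, 0.005, 0.35), "HGB": (95.0, 18.0, 40.0, 160.0),
        "NEUT%": (35.0, 12.0, 2.0, 90.0), "NEUT#": (2.4, 1.4, 0.05, 20.0),
        "LYMPH%": (30.0, 10.0, 2.0, 90.0), "MONO%": (5.0, 3.0, 0.0, 40.0),
        "IG#": (1.8, 1.2, 0.0, 15.0), "IG%": (18.0, 9.0, 0.0, 60.0),
        "MCV": (92.0, 6.0, 60.0, 120.0), "MCHC": (330.0, 12.0, 280.0, 380.0),
        "D-Neu-SFL-P": (112.0, 12.0, 40.0, 220.0),
        "D-Neu-SFL-W": (95.0, 14.0, 20.0, 250.0),
        "N-WBC-SFL-P": (118.0, 14.0, 40.0, 250.0),
        "N-WBC-SFL-W": (92.0, 14.0, 20.0, 250.0),
    },
    # AML routine values deliberately shadow the APL ones closely: platelet
    # indices, immature-granulocyte counts and CPD widths are depressed or
    # raised in both, so routine parameters alone barely separate the two
    "AML": {
        "WBC": (12.0, 9.0, 0.5, 120.0), "PLT": (68.0, 40.0, 5.0, 300.0),
        "PCT": (0.075, 0.04, 0.005, 0.35), "HGB": (92.0, 17.0, 40.0, 160.0),
        "NEUT%": (32.0, 12.0, 2.0, 90.0), "NEUT#": (2.7, 1.7, 0.05, 30.0),
        "LYMPH%": (31.0, 11.0, 2.0, 90.0), "MONO%": (7.0, 5.0, 0.0, 50.0),
        "IG#": (1.6, 1.1, 0.0, 15.0), "IG%": (16.0, 8.5, 0.0, 60.0),
        "MCV": (93.0, 7.0, 60.0, 125.0), "MCHC": (329.0, 12.0, 280.0, 380.0),
        "D-Neu-SFL-P": (108.0, 13.0, 40.0, 220.0),
        "D-Neu-SFL-W": (90.0, 14.0, 20.0, 250.0),
        "N-WBC-SFL-P": (112.0, 14.0, 40.0, 250.0),
        "N-WBC-SFL-W": (86.0, 14.0, 20.0, 250.0),
    },
    "ALL": {
        "WBC": (20.0, 16.0, 0.5, 200.0), "PLT": (85.0, 45.0, 5.0, 350.0),
        "PCT": (0.09, 0.045, 0.005, 0.40), "HGB": (95.0, 16.0, 40.0, 160.0),
        "NEUT%": (25.0, 10.0, 2.0, 90.0), "LYMPH%": (55.0, 14.0, 2.0, 98.0),
        "LYMPH#": (8.0, 6.0, 0.2, 80.0), "MONO%": (4.0, 2.5, 0.0, 30.0),
        "IG#": (0.3, 0.25, 0.0, 6.0), "IG%": (2.5, 2.0, 0.0, 30.0),
        "D-Lym-SFL-P": (88.0, 10.0, 30.0, 200.0),
        "D-Lym-SFL-W": (72.0, 10.0, 20.0, 200.0),
        "N-WBC-SFL-P": (92.0, 11.0, 40.0, 250.0),
        "N-WBC-SFL-W": (68.0, 11.0, 20.0, 250.0),
    },
}


def _build_spec(class_name: str) -> ClassSpec:
    pops: list[PopulationSpec] = []
    for channel, base in ((DIFF, _DIFF_BASE), (WNB, _WNB_BASE)):
        fracs = _class_fractions(class_name)[channel]
        for name, frac in fracs.items():
            if name in base:
                mean, sd = base[name]
                pops.append(_pop(name, channel, mean, sd, frac))
            else:
                abn = _ABN[class_name][channel]
                pops.append(PopulationSpec(abn.name, channel, abn.mean, abn.cov, frac))
    dists = dict(_ROUTINE_HC)
    dists.update(_ROUTINE_OVERRIDES.get(class_name, {}))
    abn_frac = _ABN_FRACTION[class_name]
    return ClassSpec(class_name, tuple(pops), dists,
                     n_events_scale=1.0 / (1.0 - abn_frac),
                     abn_fraction_range=_ABN_RANGE[class_name])


def default_class_specs() -> dict[str, ClassSpec]:
    """The shipped study conditions: one ClassSpec per study group."""
    return {name: _build_spec(name) for name in CLASS_NAMES}


# ---------------------------------------------------------------------------
# sampling


def sample_event_cloud(
    spec: ClassSpec, channel: str, n_events: int, rng: np.random.Generator
) -> EventCloud:
    """Draw one event cloud: multinomial population mix, per-population
    trivariate Gaussians, coordinates clipped into [0, 1)."""
    if n_events <= 0:
        raise ValidationError("n_events must be > 0")
    pops = spec.channel_populations(channel)
    if not pops:
        raise ConfigurationError(f"{spec.class_name}: no populations for {channel}")
    fracs = np.array([p.fraction for p in pops])
    counts = rng.multinomial(n_events, fracs / fracs.sum())
    coords = []
    labels = []
    for p, c in zip(pops, counts):
        if c == 0:
            continue
        xyz = rng.multivariate_normal(np.asarray(p.mean), p.cov, size=c,
                                      method="cholesky" if _is_pd(p.cov) else "svd")
        coords.append(np.clip(xyz, 0.0, np.nextafter(1.0, 0.0)))
        labels.append(np.repeat(p.name, c))
    xyz = np.concatenate(coords, axis=0)
    population = np.concatenate(labels)
    return EventCloud(channel=channel, fs=xyz[:, 0], ss=xyz[:, 1], fl=xyz[:, 2],
                      population=population)


ABNORMAL_POPULATIONS = ("AbnPromyelocyte", "Blast", "Lymphoblast")


def with_abnormal_fraction(spec: ClassSpec, severity: float) -> ClassSpec:
    """Re-mix a class spec so the abnormal populations carry ``severity``
    of each cloud while the common populations keep their absolute
    concentration (the event-count scale adjusts accordingly)."""
    if not 0.0 <= severity < 1.0:
        raise ValidationError("severity must be in [0, 1)")
    new_pops = []
    for channel in CHANNELS:
        pops = spec.channel_populations(channel)
        abn = [p for p in pops if p.name in ABNORMAL_POPULATIONS]
        common = [p for p in pops if p.name not in ABNORMAL_POPULATIONS]
        abn_total = sum(p.fraction for p in abn)
        if abn_total == 0:
            new_pops.extend(pops)
            continue
        common_total = sum(p.fraction for p in common)
        for p in common:
            new_pops.append(PopulationSpec(
                p.name, p.channel, p.mean, p.cov,
                p.fraction / common_total * (1.0 - severity)))
        for p in abn:
            new_pops.append(PopulationSpec(
                p.name, p.channel, p.mean, p.cov,
                p.fraction / abn_total * severity))
    return ClassSpec(spec.class_name, tuple(new_pops), spec.routine_param_dists,
                     n_events_scale=1.0 / (1.0 - severity),
                     abn_fraction_range=None)


def jitter_populations(spec: ClassSpec, rng: np.random.Generator,
                       sd: float = 0.025) -> ClassSpec:
    """Perturb every population mean by an isotropic Gaussian shift.

    Emulates patient-to-patient and instrument-to-instrument drift of
    cluster positions (gain/calibration differences), so no geometric
    summary of the rendered clouds is exactly reproducible across samples.
    """
    if sd == 0:
        return spec
    pops = tuple(
        PopulationSpec(
            p.name, p.channel,
            tuple(np.clip(np.asarray(p.mean) + rng.normal(0.0, sd, 3),
                          0.0, np.nextafter(1.0, 0.0))),
            p.cov, p.fraction)
        for p in spec.populations)
    return ClassSpec(spec.class_name, pops, spec.routine_param_dists,
                     spec.n_events_scale, None)


def _is_pd(cov: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(cov)
        return True
    except np.linalg.LinAlgError:
        return False


def sample_routine_params(spec: ClassSpec, rng: np.random.Generator) -> dict[str, float]:
    """Draw the 50 routine parameters from their clipped Gaussians."""
    missing = [n for n in ROUTINE_PARAM_NAMES if n not in spec.routine_param_dists]
    if missing:
        raise ConfigurationError(f"missing routine distributions for {missing}")
    out = {}
    for name in ROUTINE_PARAM_NAMES:
        mu, sd, lo, hi = spec.routine_param_dists[name]
        out[name] = float(np.clip(rng.normal(mu, sd), lo, hi))
    return out


def generate_cohort(
    n_per_class: dict[str, int],
    class_specs: dict[str, ClassSpec] | None = None,
    seed: int = 0,
    n_events: int = 12000,
    position_jitter_sd: float = 0.025,
) -> list[CohortSample]:
    """Generate a seeded synthetic cohort.

    Samples are emitted class-by-class in the order given by ``n_per_class``;
    the whole cohort is a deterministic function of (specs, seed, n_events,
    jitter).  Per sample, the abnormal-cell burden is drawn from the class's
    severity range and every cluster position receives a small random shift.
    """
    specs = class_specs if class_specs is not None else default_class_specs()
    for cls in n_per_class:
        if cls not in specs:
            raise ConfigurationError(f"no ClassSpec for class {cls!r}")
        if n_per_class[cls] < 0:
            raise ValidationError("class counts must be >= 0")
    rng = np.random.default_rng(seed)
    cohort: list[CohortSample] = []
    for cls, n in n_per_class.items():
        spec = specs[cls]
        for i in range(n):
            sid = f"{cls}-{i:04d}"
            draw = spec
            if spec.abn_fraction_range is not None:
                lo, hi = spec.abn_fraction_range
                draw = with_abnormal_fraction(spec, float(rng.uniform(lo, hi)))
            draw = jitter_populations(draw, rng, position_jitter_sd)
            n_ev = max(1, round(n_events * draw.n_events_scale))
            diff = sample_event_cloud(draw, DIFF, n_ev, rng)
            wnb = sample_event_cloud(draw, WNB, n_ev, rng)
            diff.sample_id = wnb.sample_id = sid
            params = sample_routine_params(spec, rng)
            cohort.append(CohortSample(sid, cls, diff, wnb, params))
    return cohort


# ---------------------------------------------------------------------------
# spec-file round trip (YAML)


def dump_class_specs(specs: dict[str, ClassSpec], path) -> None:
    doc = {}
    for cls, spec in specs.items():
        doc[cls] = {
            "populations": [
                {"name": p.name, "channel": p.channel, "mean": list(map(float, p.mean)),
                 "cov": np.asarray(p.cov).tolist(), "fraction": float(p.fraction)}
                for p in spec.populations
            ],
            "routine_param_dists": {
                k: list(map(float, v)) for k, v in spec.routine_param_dists.items()
            },
            "n_events_scale": float(spec.n_events_scale),
            "abn_fraction_range": (None if spec.abn_fraction_range is None
                                   else list(map(float, spec.abn_fraction_range))),
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_class_specs(path) -> dict[str, ClassSpec]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    specs = {}
    for cls, d in doc.items():
        pops = tuple(
            PopulationSpec(p["name"], p["channel"], tuple(p["mean"]),
                           np.asarray(p["cov"]), p["fraction"])
            for p in d["populations"]
        )
        dists = {k: tuple(v) for k, v in d["routine_param_dists"].items()}
        rng_field = d.get("abn_fraction_range")
        specs[cls] = ClassSpec(cls, pops, dists,
                               n_events_scale=d.get("n_events_scale", 1.0),
                               abn_fraction_range=(None if rng_field is None
                                                   else tuple(rng_field)))
    return specs


def cohort_to_frame(cohort: list[CohortSample]):
    """Routine-parameter table: one row per sample (sample_id, class, 50 params)."""
    import pandas as pd

    rows = []
    for s in cohort:
        row = {"sample_id": s.sample_id, "class": s.class_name}
        row.update(s.routine_params)
        rows.append(row)
    return pd.DataFrame(rows)
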