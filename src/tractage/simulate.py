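"""Synthetic developmental cohort generator.

Generates cohorts whose statistical structure matches what the downstream
stages assume, so the whole pipeline can be exercised without restricted
data: sigmoidal FA maturation along 54 white-matter tracts (100 nodes
each), additive/multiplicative site effects, subject-level maturational
deviations shared within tract systems (the planted ground-truth
brain-age gap), two latent modes coupling those deviations to behavior
blocks, liability-threshold psychiatric diagnosis counts at two visits,
and puberty/hormone variables correlated with age and deviation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

__all__ = [
    "TractInfo",
    "GrowthParams",
    "ModeSpec",
    "LiabilitySpec",
    "CohortConfig",
    "default_tract_catalog",
    "default_growth_params",
    "growth_curve",
    "simulate_cohort",
    "simulate_puberty_hormones",
    "write_cohort",
    "read_cohort",
    "write_profiles",
    "read_profiles",
    "write_config",
    "read_config",
]

SYSTEMS = (
    "dorsal-association",
    "ventral-association",
    "limbic",
    "sensorimotor",
    "thalamic",
    "corticostriatal",
    "callosal",
)

# Hormone plausibility ranges used for quality control, pg/ml.
HORMONE_RANGES = {
    "dhea": (5.0, 1000.0),
    "testosterone": (5.0, 500.0),
    "estradiol": (0.0, 1500.0),
}


@dataclass(frozen=True)
class TractInfo:
    """One tract of the catalog: name, tract-system label, laterality."""

    name: str
    system: str
    bilateral: bool = True

    def __post_init__(self) -> None:
        if self.system not in SYSTEMS:
            raise ValueError(f"unknown tract system: {self.system!r}")


def default_tract_catalog() -> list[TractInfo]:
    """The 29-entry tract catalog: 25 bilateral pairs plus 4 callosal tracts.

    Expanding bilateral entries into left/right instances yields 54 tracts.
    """
    pairs = {
        "dorsal-association": ["AF", "FAT", "PAT", "SLF1", "SLF2", "SLF3"],
        "ventral-association": ["IFOF", "ILF", "UF", "MdLF"],
        "limbic": ["C_FPH", "C_FP", "C_PH", "C_PHP", "C_PO", "F"],
        "sensorimotor": ["CST", "OR", "VOF"],
        "thalamic": ["TR_A", "TR_P", "TR_S"],
        "corticostriatal": ["CS_A", "CS_P", "CS_S"],
    }
    catalog = [
        TractInfo(name, system, bilateral=True)
        for system, names in pairs.items()
        for name in names
    ]
    catalog += [
        TractInfo(name, "callosal", bilateral=False)
        for name in ["CC_Body", "CC_Major", "CC_Minor", "CC_Tap"]
    ]
    return catalog


def expand_hemispheres(catalog: list[TractInfo]) -> list[tuple[str, str, str]]:
    """Expand the catalog into (tract, hemisphere, system) unilateral units.

    Bilateral tracts yield 'L' and 'R' instances; callosal tracts a single
    'M' (midline) instance.
    """
    units = []
    for t in catalog:
        if t.bilateral:
            units.append((t.name, "L", t.system))
            units.append((t.name, "R", t.system))
        else:
            units.append((t.name, "M", t.system))
    return units


@dataclass
class GrowthParams:
    """Logistic FA maturation parameters, one value per tract node.

    f0 is the childhood FA floor, f1 the adult ceiling, k the maturation
    rate (1/years) and t0 the age (years) of fastest growth.
    """

    f0: np.ndarray
    f1: np.ndarray
    k: np.ndarray
    t0: np.ndarray

    def validate(self) -> None:
        arrays = [np.asarray(a, float) for a in (self.f0, self.f1, self.k, self.t0)]
        if any(not np.all(np.isfinite(a)) for a in arrays):
            raise ValueError("growth parameters must be finite")
        f0, f1, k, _ = arrays
        if np.any(k <= 0):
            raise ValueError("growth rate k must be positive")
        if np.any(f0 >= f1):
            raise ValueError("FA floor f0 must be below ceiling f1")
        if np.any(f0 < 0) or np.any(f1 > 1):
            raise ValueError("FA bounds must lie in [0, 1]")


def growth_curve(age, params: GrowthParams | tuple) -> np.ndarray:
    """Logistic FA maturation: f0 + (f1 - f0) / (1 + exp(-k (age - t0))).

    Monotone increasing in age with asymptotes f0 (childhood) and f1
    (adulthood); the midpoint (f0+f1)/2 is reached at age t0.
    """
    if not isinstance(params, GrowthParams):
        f0, f1, k, t0 = params
        params = GrowthParams(*(np.asarray(v, float) for v in (f0, f1, k, t0)))
    params.validate()
    age = np.asarray(age, float)
    if not np.all(np.isfinite(age)):
        raise ValueError("age must be finite")
    return params.f0 + (params.f1 - params.f0) * expit(params.k * (age - params.t0))


def default_growth_params(
    n_tracts: int, nodes_per_tract: int, seed: int = 7
) -> GrowthParams:
    """Realistic per-tract-node logistic parameters.

    Floors/ceilings vary across tracts and smoothly along nodes (tract
    profiles are lower near cortical endpoints); maturation midpoints span
    late childhood to mid-adolescence, matching the protracted maturation
    of association tracts relative to sensorimotor ones.
    """
    rng = np.random.default_rng(seed)
    node = np.linspace(0.0, 1.0, nodes_per_tract)
    bump = 0.08 * np.sin(np.pi * node)  # mid-tract FA higher than endpoints
    f0 = rng.uniform(0.22, 0.32, n_tracts)[:, None] + bump
    f1 = f0 + rng.uniform(0.12, 0.22, n_tracts)[:, None]
    k = np.broadcast_to(rng.uniform(0.25, 0.6, n_tracts)[:, None], f0.shape).copy()
    t0 = (
        rng.uniform(9.0, 14.0, n_tracts)[:, None]
        + rng.normal(0.0, 0.3, (n_tracts, nodes_per_tract))
    )
    return GrowthParams(f0=f0, f1=f1, k=k, t0=t0)


@dataclass
class ModeSpec:
    """A planted latent mode linking tract-system deviations to a behavior block.

    The latent score is the standardized mean deviation over ``systems``;
    every behavior column in ``block`` carries a common component with
    correlation ``coupling`` to the latent score.
    """

    name: str
    systems: tuple[str, ...]
    block: str  # behavior block name: "cognition" or "psychopathology"
    coupling: float = 0.3

    def validate(self) -> None:
        if not -1.0 < self.coupling < 1.0:
            raise ValueError("|coupling| must be < 1")
        for s in self.systems:
            if s not in SYSTEMS:
                raise ValueError(f"unknown system {s!r}")


@dataclass
class LiabilitySpec:
    """Liability-threshold model for cumulative diagnosis counts at two visits.

    Liability is standard normal: -weight * (standardized deviation over
    ``systems``) plus independent noise. Baseline/follow-up class
    probabilities give the marginal P(0), P(1), P(>=2) diagnosis classes;
    follow-up liability correlates ``followup_corr`` with baseline,
    producing all four healthy/diagnosed transition cells.
    """

    weight: float = 0.5
    systems: tuple[str, ...] = ("dorsal-association", "ventral-association")
    baseline_probs: tuple[float, float, float] = (0.752, 0.156, 0.092)
    followup_probs: tuple[float, float, float] = (0.795, 0.141, 0.064)
    followup_corr: float = 0.6

    def validate(self) -> None:
        if not 0.0 <= abs(self.weight) < 1.0:
            raise ValueError("|weight| must be < 1")
        for probs in (self.baseline_probs, self.followup_probs):
            if abs(sum(probs) - 1.0) > 1e-8 or min(probs) <= 0:
                raise ValueError("class probabilities must be positive and sum to 1")
        if not -1.0 < self.followup_corr < 1.0:
            raise ValueError("|followup_corr| must be < 1")


def _default_modes() -> list[ModeSpec]:
    return [
        ModeSpec(
            "association",
            ("dorsal-association", "ventral-association"),
            block="cognition",
            coupling=0.3,
        ),
        ModeSpec(
            "subcortical-limbic",
            ("limbic", "sensorimotor", "thalamic", "corticostriatal", "callosal"),
            block="psychopathology",
            coupling=0.3,
        ),
    ]


@dataclass
class CohortConfig:
    """Full parameterization of the synthetic cohort.

    Defaults emulate a developmental sample: n=600 subjects aged 6-22
    years over 3 acquisition sites, 54 tracts x 100 nodes, tract-system
    maturational deviations of SD 2 years with small tract-level jitter,
    per-node FA noise of SD 0.04, and mild site location/scale effects.
    """

    n_subjects: int = 600
    age_range: tuple[float, float] = (6.0, 22.0)
    n_sites: int = 3
    tract_catalog: list[TractInfo] = field(default_factory=default_tract_catalog)
    nodes_per_tract: int = 100
    growth_seed: int = 7
    deviation_sd: float = 2.0  # years, shared within tract system
    mode_share: float = 0.5  # fraction of system-deviation variance shared across a mode's systems
    tract_jitter_sd: float = 0.25  # years, tract-level jitter around system deviation
    noise_sd: float = 0.04  # FA units, i.i.d. per node
    tract_noise_sd: float = 0.02  # FA units, shared across a tract's nodes per subject
    site_location_sd: float = 0.02  # FA units, per-site per-feature shift
    site_scale_sd: float = 0.25  # log-scale SD of per-site residual-scale factor
    n_cognitive: int = 20
    n_psychopathology: int = 31
    behavior_noise_sd: float = 0.3  # unique noise per behavior column
    modes: list[ModeSpec] = field(default_factory=_default_modes)
    liability: LiabilitySpec = field(default_factory=LiabilitySpec)
    followup_years: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range min must be below max")
        if self.nodes_per_tract < 2:
            raise ValueError("nodes_per_tract must be >= 2")
        if self.n_sites < 1:
            raise ValueError("need at least 1 site")
        for v in (self.deviation_sd, self.tract_jitter_sd, self.noise_sd,
                  self.tract_noise_sd, self.site_location_sd, self.site_scale_sd,
                  self.behavior_noise_sd):
            if v < 0 or not np.isfinite(v):
                raise ValueError("variance parameters must be finite and >= 0")
        if self.deviation_sd == 0 and self.tract_jitter_sd == 0 and self.noise_sd == 0:
            # downstream models need some variation beyond age
            pass
        for m in self.modes:
            m.validate()
        self.liability.validate()

    @property
    def units(self) -> list[tuple[str, str, str]]:
        return expand_hemispheres(self.tract_catalog)

    @property
    def n_units(self) -> int:
        return len(self.units)

    def growth_params(self) -> GrowthParams:
        return default_growth_params(self.n_units, self.nodes_per_tract, self.growth_seed)


def _feature_index(config: CohortConfig) -> pd.MultiIndex:
    tuples = [
        (tract, hemi, node + 1)
        for tract, hemi, _system in config.units
        for node in range(config.nodes_per_tract)
    ]
    return pd.MultiIndex.from_tuples(tuples, names=["tract", "hemisphere", "node"])


def tract_systems(config: CohortConfig) -> pd.Series:
    """Map (tract, hemisphere) unit -> system label."""
    return pd.Series(
        {(t, h): s for t, h, s in config.units}, name="system"
    )


def simulate_cohort(
    config: CohortConfig,
    include_profiles: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame | None, pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort under ``config``.

    Returns
    -------
    cohort : DataFrame, one row per subject (baseline covariates) with the
        planted per-system deviations (columns ``dev_<system>``).
    profiles : DataFrame, subjects x (tract, hemisphere, node) FA values at
        baseline, site effects and noise applied, clipped to [0, 1]
        (``profiles.attrs["n_clipped"]`` records how many values clipped).
    behavior : DataFrame, subjects x 51 behavioral scores (20 cognitive +
        31 psychopathology by default).
    diagnoses : DataFrame, per subject: diagnosis count class at baseline
        and follow-up and the HH/PH/HP/PP transition class.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    lo, hi = config.age_range

    subject_id = np.array([f"sub-{i:05d}" for i in range(n)])
    age = rng.uniform(lo, hi, n)
    sex = rng.integers(0, 2, n)  # 0 = female, 1 = male
    site = rng.integers(0, config.n_sites, n)

    units = config.units
    n_units = len(units)
    systems = np.array([s for _, _, s in units])

    # Tract-system-level maturational deviation (years), shared across the
    # tracts of a system, plus small tract-level jitter. Systems belonging
    # to a latent mode's mask share a mode-level factor (fraction
    # ``mode_share`` of the deviation variance), so that the planted
    # brain-behavior modes load on whole tract systems.
    if not 0.0 <= config.mode_share <= 1.0:
        raise ValueError("mode_share must lie in [0, 1]")
    mode_of_system = {}
    for mode in config.modes:
        for s in mode.systems:
            mode_of_system.setdefault(s, mode.name)
    mode_factor = {m.name: rng.normal(0.0, 1.0, n) for m in config.modes}
    sys_dev = {}
    for s in SYSTEMS:
        eps = rng.normal(0.0, 1.0, n)
        m = mode_of_system.get(s)
        if m is None or config.mode_share == 0:
            sys_dev[s] = config.deviation_sd * eps
        else:
            sys_dev[s] = config.deviation_sd * (
                np.sqrt(config.mode_share) * mode_factor[m]
                + np.sqrt(1.0 - config.mode_share) * eps
            )
    unit_dev = np.empty((n, n_units))
    for j, (_, _, s) in enumerate(units):
        unit_dev[:, j] = sys_dev[s] + rng.normal(0.0, config.tract_jitter_sd, n)

    profiles = None
    if include_profiles:
        params = config.growth_params()
        nodes = config.nodes_per_tract
        values = np.empty((n, n_units * nodes))
        for j in range(n_units):
            p = GrowthParams(
                f0=params.f0[j], f1=params.f1[j], k=params.k[j], t0=params.t0[j]
            )
            # effective maturational age for this tract = age + deviation
            eff_age = age[:, None] + unit_dev[:, j][:, None]
            values[:, j * nodes : (j + 1) * nodes] = growth_curve(eff_age, p)

        n_features = values.shape[1]
        # Site effects: additive location shift and multiplicative residual
        # scale; measurement noise has a node-level i.i.d. part and a
        # tract-level part shared along the tract (noise along real tract
        # profiles is spatially correlated).
        shift = rng.normal(0.0, config.site_location_sd, (config.n_sites, n_features))
        scale = np.exp(
            rng.normal(0.0, config.site_scale_sd, (config.n_sites, n_features))
        )
        noise = rng.normal(0.0, config.noise_sd, values.shape)
        noise += np.repeat(
            rng.normal(0.0, config.tract_noise_sd, (n, n_units)), nodes, axis=1
        )
        values = values + shift[site] + scale[site] * noise

        clipped = int(np.sum((values < 0) | (values > 1)))
        values = np.clip(values, 0.0, 1.0)

        profiles = pd.DataFrame(
            values, index=subject_id, columns=_feature_index(config)
        )
        profiles.index.name = "subject_id"
        profiles.attrs["n_clipped"] = clipped

    # Behavior: latent score per mode = standardized mean system deviation
    # over the mode's mask; a block-shared component carries the coupling.
    n_cog, n_psy = config.n_cognitive, config.n_psychopathology
    col_names = [f"cog_{i + 1:02d}" for i in range(n_cog)] + [
        f"psy_{i + 1:02d}" for i in range(n_psy)
    ]
    blocks = {"cognition": col_names[:n_cog], "psychopathology": col_names[n_cog:]}
    behavior = pd.DataFrame(
        rng.normal(0.0, 1.0, (n, n_cog + n_psy)), index=subject_id, columns=col_names
    )
    behavior.index.name = "subject_id"
    latents = {}
    for mode in config.modes:
        lat = np.mean([sys_dev[s] for s in mode.systems], axis=0)
        sd = lat.std()
        if sd == 0:
            if mode.coupling != 0:
                raise ValueError(
                    "degenerate config: zero deviation variance with nonzero coupling"
                )
            lat = np.zeros(n)
        else:
            lat = (lat - lat.mean()) / sd
        latents[mode.name] = lat
        r = mode.coupling
        shared = r * lat + np.sqrt(1.0 - r**2) * rng.normal(0.0, 1.0, n)
        for col in blocks[mode.block]:
            behavior[col] = shared + config.behavior_noise_sd * rng.normal(0.0, 1.0, n)
    behavior.attrs["latents"] = latents
    behavior.attrs["blocks"] = blocks

    # Diagnosis counts via liability thresholding; lower deviation in the
    # targeted systems raises liability (delayed maturation -> more diagnoses).
    lia = config.liability
    lat = np.mean([sys_dev[s] for s in lia.systems], axis=0)
    sd = lat.std()
    lat = (lat - lat.mean()) / sd if sd > 0 else np.zeros(n)
    w = lia.weight
    liab_base = -w * lat + np.sqrt(1.0 - w**2) * rng.normal(0.0, 1.0, n)
    rho = lia.followup_corr
    liab_follow = rho * liab_base + np.sqrt(1.0 - rho**2) * rng.normal(0.0, 1.0, n)

    def classify(liab: np.ndarray, probs: tuple[float, float, float]) -> np.ndarray:
        from scipy.stats import norm

        c0 = norm.ppf(probs[0])  # below -> 0 diagnoses
        c1 = norm.ppf(probs[0] + probs[1])  # below -> 1 diagnosis
        cls = np.zeros(len(liab), dtype=int)
        cls[liab >= c0] = 1
        cls[liab >= c1] = 2
        return cls

    base_cls = classify(liab_base, lia.baseline_probs)
    follow_cls = classify(liab_follow, lia.followup_probs)
    trans = np.where(
        base_cls == 0,
        np.where(follow_cls == 0, "HH", "HP"),
        np.where(follow_cls == 0, "PH", "PP"),
    )
    diagnoses = pd.DataFrame(
        {
            "subject_id": subject_id,
            "diagnosis_count_baseline": base_cls,
            "diagnosis_count_followup": follow_cls,
            "transition": trans,
        }
    ).set_index("subject_id")

    cohort = pd.DataFrame(
        {
            "subject_id": subject_id,
            "age": age,
            "sex": sex,
            "site": np.char.add("site-", site.astype(str)),
        }
    ).set_index("subject_id")
    for s in SYSTEMS:
        cohort[f"dev_{s}"] = sys_dev[s]
    for name, lat in latents.items():
        cohort[f"latent_{name}"] = lat

    return cohort, profiles, behavior, diagnoses


def bag_feature_standins(
    cohort: pd.DataFrame,
    config: CohortConfig,
    estimation_noise_sd: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-tract corrected-BAG stand-ins: planted deviation + estimation noise.

    One column per catalog entry (bilateral pairs pooled, as in the
    brain-age models) holding the tract system's planted deviation plus
    i.i.d. measurement noise (years). Emulates the output of the GP/BAG
    stage at a configurable estimation accuracy, for exercising the
    downstream multivariate and group analyses at scale.
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    n = len(cohort)
    cols = {}
    for t in config.tract_catalog:
        dev = cohort[f"dev_{t.system}"].to_numpy()
        cols[t.name] = dev + rng.normal(0.0, estimation_noise_sd, n)
    return pd.DataFrame(cols, index=cohort.index)


# ---------------------------------------------------------------------------
# Puberty and hormones
# ---------------------------------------------------------------------------

def simulate_puberty_hormones(
    cohort: pd.DataFrame,
    config: CohortConfig,
    age_coupling: float = 0.8,
    deviation_coupling: float = 0.15,
    seed: int | None = None,
) -> pd.DataFrame:
    """Two-visit table of PDS items, hormone levels and collection covariates.

    One row per subject-visit (baseline and 2-year follow-up). PDS item
    scores increase stochastically with age and with the subject's
    association-system deviation; salivary hormone levels are log-normal,
    increase with age, and are truncated to the plausibility ranges used
    for quality control (DHEA 5-1000, testosterone 5-500, estradiol
    0-1500 pg/ml).
    """
    if "age" not in cohort.columns:
        raise ValueError("cohort must contain an 'age' column")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    rows = []
    dev = cohort.get("dev_dorsal-association", pd.Series(0.0, index=cohort.index))
    for visit, dt in (("baseline", 0.0), ("followup2y", config.followup_years)):
        age = cohort["age"].to_numpy() + dt
        sex = cohort["sex"].to_numpy()
        n = len(age)
        # latent pubertal maturation, increasing in age and deviation
        z = (
            age_coupling * (age - 12.0) / 3.0
            + deviation_coupling * dev.to_numpy() / max(config.deviation_sd, 1e-12)
            + rng.normal(0.0, 0.5, n)
        )

        def items(z, n_items, rng):
            # each PDS item in 1..4, cut from a jittered copy of the latent
            cuts = np.array([-1.0, 0.0, 1.0])
            out = np.empty((len(z), n_items), dtype=int)
            for i in range(n_items):
                zi = z + rng.normal(0.0, 0.3, len(z))
                out[:, i] = 1 + np.searchsorted(cuts, zi, side="right").clip(0, 3)
            return out

        male_items = items(z, 3, rng)
        female_items = items(z, 2, rng)
        menarche = ((z + rng.normal(0, 0.3, n)) > 0.2) & (sex == 0)

        def hormone(name, base, slope, sd):
            lo_h, hi_h = HORMONE_RANGES[name]
            level = np.exp(base + slope * (age - 12.0) + rng.normal(0.0, sd, n))
            return np.clip(level, lo_h if lo_h > 0 else 0.0, hi_h)

        df = pd.DataFrame(
            {
                "subject_id": cohort.index,
                "visit": visit,
                "age": age,
                "sex": sex,
                "pds_m1": male_items[:, 0],
                "pds_m2": male_items[:, 1],
                "pds_m3": male_items[:, 2],
                "pds_f1": female_items[:, 0],
                "pds_f2": female_items[:, 1],
                "menarche": menarche.astype(int),
                "dhea": hormone("dhea", np.log(60.0), 0.15 * age_coupling, 0.5),
                "testosterone": hormone(
                    "testosterone", np.log(30.0), 0.18 * age_coupling, 0.5
                ),
                "estradiol": np.where(
                    sex == 0,
                    hormone("estradiol", np.log(120.0), 0.12 * age_coupling, 0.5),
                    hormone("estradiol", np.log(60.0), 0.05 * age_coupling, 0.5),
                ),
                "caffeine_intake": rng.integers(0, 2, n),
                "physical_activity": rng.integers(0, 2, n),
                "collection_time": rng.uniform(420.0, 1140.0, n),  # minutes past midnight
                "collection_duration": rng.uniform(2.0, 10.0, n),
                "freeze_time": rng.uniform(30.0, 600.0, n),
            }
        )
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    # sex-specific PDS sum: males 3 items (3..12), females 2 items (2..8)
    out["pds_sum"] = np.where(
        out["sex"] == 1,
        out[["pds_m1", "pds_m2", "pds_m3"]].sum(axis=1),
        out[["pds_f1", "pds_f2"]].sum(axis=1),
    )
    return out


# ---------------------------------------------------------------------------
# Round-tripping TSV / YAML
# ---------------------------------------------------------------------------

def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_profiles(profiles: pd.DataFrame, path) -> None:
    """Profiles TSV with a 3-level header (tract, hemisphere, node)."""
    profiles.to_csv(path, sep="\t")


def read_profiles(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=[0, 1, 2], index_col=0)
    df.columns = pd.MultiIndex.from_tuples(
        [(t, h, int(n)) for t, h, n in df.columns],
        names=["tract", "hemisphere", "node"],
    )
    df.index.name = "subject_id"
    return df


def write_config(config: CohortConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["tract_catalog"] = [
        {"name": t.name, "system": t.system, "bilateral": t.bilateral}
        for t in config.tract_catalog
    ]
    d["modes"] = [dataclasses.asdict(m) for m in config.modes]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def read_config(path) -> CohortConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["tract_catalog"] = [TractInfo(**t) for t in d["tract_catalog"]]
    modes = []
    for m in d["modes"]:
        m["systems"] = tuple(m["systems"])
        modes.append(ModeSpec(**m))
    d["modes"] = modes
    lia = d["liability"]
    for key in ("systems", "baseline_probs", "followup_probs"):
        lia[key] = tuple(lia[key])
    d["liability"] = LiabilitySpec(**lia)
    d["age_range"] = tuple(d["age_range"])
    return CohortConfig(**d)
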