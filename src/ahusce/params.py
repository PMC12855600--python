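"""Model inputs: parameter specifications, uncertainty distributions, settings.

Every quantity entering the decision model is declared as a
:class:`ParameterSpec` — a mean, a standard error and a sampling family used
by the probabilistic sensitivity analysis (PSA).  Probabilities and
proportions are sampled from moment-matched Beta distributions, costs from
Gamma distributions (negated for cost offsets with negative means), the
transplant-failure fraction from a moment-matched lognormal, and utility
increments/decrements from Normals.  Parameters whose variation was never
quantified default to a standard error of 10% of the mean; parameters marked
``fixed`` are never sampled.

The bundled parameter file ``data/parameters.yaml`` carries the full
published input table for the aHUS eculizumab-withdrawal model and is the
default source for :func:`load_parameters`.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import yaml

FAMILIES = ("beta", "gamma", "normal", "lognormal", "fixed")

#: Default relative SE applied when a spec omits its standard error.
DEFAULT_SE_FRACTION = 0.10


class ParameterError(ValueError):
    """A parameter specification violates its domain constraints."""


@dataclass
class ParameterSpec:
    """One model input: point estimate plus PSA sampling family.

    ``negated`` marks gamma-family cost offsets with negative means: the
    gamma is parameterised on ``|mean|`` and draws are negated after
    sampling, preserving both the published family and the sign.
    """

    name: str
    mean: float
    se: float | None = None
    family: str = "fixed"
    units: str = ""
    negated: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ParameterError(f"{self.name}: unknown family {self.family!r}")
        if self.se is None:
            self.se = 0.0 if self.family == "fixed" else DEFAULT_SE_FRACTION * abs(self.mean)
        if self.se < 0:
            raise ParameterError(f"{self.name}: negative se {self.se}")
        if self.family == "fixed" and self.se != 0:
            raise ParameterError(f"{self.name}: fixed parameters must have se = 0")
        if self.family == "beta":
            if not 0 < self.mean < 1:
                raise ParameterError(f"{self.name}: beta mean {self.mean} outside (0, 1)")
            if self.se > 0 and self.se**2 >= self.mean * (1 - self.mean):
                raise ParameterError(
                    f"{self.name}: beta variance {self.se**2:.4g} infeasible, "
                    f"needs se^2 < mean(1-mean) = {self.mean * (1 - self.mean):.4g}"
                )
        if self.family in ("gamma", "lognormal") and self.mean == 0:
            raise ParameterError(f"{self.name}: {self.family} undefined for mean 0")
        self.negated = self.family == "gamma" and self.mean < 0

    def sampler(self, seed: int | np.random.Generator) -> Iterator[float]:
        """Infinite reproducible stream of draws from this spec."""
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        while True:
            yield self.draw(rng)

    def draw(self, rng: np.random.Generator, size: int | None = None):
        """Draw from the spec's PSA distribution."""
        if self.family == "fixed" or self.se == 0:
            return self.mean if size is None else np.full(size, self.mean)
        if self.family == "beta":
            a, b = beta_from_moments(self.mean, self.se)
            return rng.beta(a, b, size)
        if self.family == "gamma":
            shape, scale, negated = gamma_from_moments(self.mean, self.se)
            x = rng.gamma(shape, scale, size)
            return -x if negated else x
        if self.family == "normal":
            return rng.normal(self.mean, self.se, size)
        if self.family == "lognormal":
            mu, sig = lognormal_from_moments(self.mean, self.se)
            return rng.lognormal(mu, sig, size)
        raise ParameterError(f"{self.name}: unknown family {self.family!r}")


def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Beta shape parameters (alpha, beta) reproducing ``mean`` and ``se``."""
    if not 0 < mean < 1:
        raise ParameterError(f"beta mean {mean} outside (0, 1)")
    var = se**2
    if not 0 < var < mean * (1 - mean):
        raise ParameterError(
            f"beta variance {var:.4g} infeasible: needs 0 < se^2 < mean(1-mean)"
        )
    nu = mean * (1 - mean) / var - 1.0
    return mean * nu, (1 - mean) * nu


def gamma_from_moments(mean: float, se: float) -> tuple[float, float, bool]:
    """Gamma (shape, scale, negated) matching ``|mean|`` and ``se``.

    Negative means are handled by fitting the gamma on the absolute value
    and flagging the draws for negation.
    """
    if mean == 0:
        raise ParameterError("gamma undefined for mean 0")
    if se <= 0:
        raise ParameterError("gamma requires se > 0")
    m = abs(mean)
    return m**2 / se**2, se**2 / m, mean < 0


def lognormal_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of a lognormal with the given natural-scale moments."""
    if mean <= 0:
        raise ParameterError("lognormal requires mean > 0")
    s2 = math.log1p((se / mean) ** 2)
    return math.log(mean) - s2 / 2, math.sqrt(s2)


def make_sampler(spec: ParameterSpec, seed: int) -> Iterator[float]:
    """Reproducible draw stream for a single spec (see :meth:`ParameterSpec.sampler`)."""
    return spec.sampler(seed)


@dataclass
class ModelConfig:
    """Model settings: cohort, cycle structure, discounting and options.

    The cohort enters at ``starting_age`` and is simulated in
    ``cycle_length_days`` steps until ``horizon_age``, with all outputs
    discounted at ``discount_rate`` per year.  ``wtp_grid`` is the
    willingness-to-pay grid (GBP per QALY) used for net-monetary-benefit
    summaries and the acceptability curve.
    """

    starting_age: float = 20.0
    male_fraction: float = 0.51
    cycle_length_days: float = 14.0
    discount_rate: float = 0.035
    horizon_age: float = 100.0
    half_cycle_correction: bool = True
    wtp_grid: tuple[float, ...] = tuple(float(x) for x in range(0, 250_001, 1000))
    # utility age decline: general-population quadratic, normalised at starting age
    utility_age_adjustment: bool = True
    # relapse utility decrement: one cycle at diagnosis ("transient") or for
    # all post-relapse cycles ("persistent")
    relapse_disutility_mode: str = "transient"
    # relapse management cost offset applies to all post-relapse cycles
    relapse_cost_mode: str = "persistent"
    # graft failure in the transplant tunnel cycle, or literally every cycle
    transplant_failure_mode: str = "tunnel"
    # advanced-disease progression (CKD4->ESRD, ESRD->transplant) supplied as
    # annual probabilities and converted per cycle; False reads them as
    # per-cycle probabilities verbatim
    advanced_progression_annual: bool = True

    def __post_init__(self) -> None:
        if self.horizon_age <= self.starting_age:
            raise ParameterError("horizon_age must exceed starting_age")
        if self.discount_rate < 0:
            raise ParameterError("discount_rate must be >= 0")
        if self.cycle_length_days <= 0:
            raise ParameterError("cycle_length_days must be > 0")
        if self.relapse_disutility_mode not in ("transient", "persistent"):
            raise ParameterError("relapse_disutility_mode must be transient|persistent")
        if self.transplant_failure_mode not in ("tunnel", "per_cycle"):
            raise ParameterError("transplant_failure_mode must be tunnel|per_cycle")

    @property
    def cycles_per_year(self) -> float:
        return 365.25 / self.cycle_length_days

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_days / 365.25

    @property
    def n_cycles(self) -> int:
        return math.ceil((self.horizon_age - self.starting_age) * self.cycles_per_year)


#: Parameter names that must be present in any complete parameter file.
MANDATORY_NAMES = (
    "pct_ckd02",
    "relapse_progression_ckd02",
    "relapse_progression_ckd3",
    "ckd4_to_esrd",
    "esrd_to_transplant",
    "transplant_failure",
    "excess_mortality_esrd",
    "excess_mortality_transplant",
    "excess_mortality_post_transplant",
    "utility_baseline_ckd03",
    "utility_transplant_procedure",
    "utility_withdrawal_increment",
    "utility_relapse_decrement",
    "disutility_ckd4",
    "disutility_esrd",
    "disutility_post_transplant",
    "cost_eculizumab_vial",
    "cost_ravulizumab_vial",
    "pct_home_delivery",
    "cost_hospital_delivery",
    "cost_antibiotics",
    "cost_monitoring_maintenance",
    "cost_monitoring_withdrawal_month1",
    "cost_monitoring_withdrawal_months2_8",
    "cost_monitoring_withdrawal_month8plus",
    "cost_management_withdrawal",
    "cost_management_relapse",
    "cost_management_ckd4",
    "cost_management_esrd",
    "cost_transplant",
    "cost_management_post_transplant",
)


@dataclass
class ParameterSet:
    """A validated collection of :class:`ParameterSpec` plus model settings."""

    specs: dict[str, ParameterSpec]
    config: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self) -> None:
        missing = [n for n in MANDATORY_NAMES if n not in self.specs]
        if missing:
            raise ParameterError(f"missing mandatory parameters: {', '.join(missing)}")

    def __getitem__(self, name: str) -> ParameterSpec:
        return self.specs[name]

    def value(self, name: str) -> float:
        return self.specs[name].mean

    def point_values(self) -> dict[str, float]:
        """All parameter means — the deterministic evaluation, seed-invariant."""
        return {n: s.mean for n, s in self.specs.items()}

    def sample(self, rng: np.random.Generator) -> dict[str, float]:
        """One joint PSA draw (independent across parameters)."""
        return {n: float(s.draw(rng)) for n, s in self.specs.items()}

    def with_overrides(self, **overrides: float) -> "ParameterSet":
        """Copy with some parameter means replaced (SEs kept)."""
        specs = copy.deepcopy(self.specs)
        for name, mean in overrides.items():
            if name not in specs:
                raise ParameterError(f"unknown parameter {name!r}")
            old = specs[name]
            specs[name] = ParameterSpec(
                name=old.name, mean=float(mean), se=old.se, family=old.family,
                units=old.units,
            )
        return ParameterSet(specs=specs, config=self.config)

    def with_config(self, **kwargs) -> "ParameterSet":
        return ParameterSet(specs=copy.deepcopy(self.specs), config=replace(self.config, **kwargs))

    def to_mapping(self) -> dict:
        out: dict = {"config": {
            "starting_age": self.config.starting_age,
            "male_fraction": self.config.male_fraction,
            "cycle_length_days": self.config.cycle_length_days,
            "discount_rate": self.config.discount_rate,
            "horizon_age": self.config.horizon_age,
            "half_cycle_correction": self.config.half_cycle_correction,
        }, "parameters": {}}
        for n, s in self.specs.items():
            out["parameters"][n] = {
                "mean": s.mean, "se": s.se, "family": s.family, "units": s.units,
            }
        return out

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_mapping(), sort_keys=False))


def _default_parameter_text() -> str:
    return resources.files("ahusce.data").joinpath("parameters.yaml").read_text()


def load_parameters(
    source: str | Path | Mapping | None = None,
    overrides: Mapping[str, float] | None = None,
    config_overrides: Mapping | None = None,
) -> ParameterSet:
    """Load and validate a parameter set.

    Parameters
    ----------
    source
        Path to a YAML/JSON parameter file, an already-parsed mapping, or
        ``None`` for the bundled published input table.
    overrides
        ``name -> mean`` replacements applied after loading.
    config_overrides
        Replacements for :class:`ModelConfig` fields.
    """
    if source is None:
        raw = yaml.safe_load(_default_parameter_text())
    elif isinstance(source, Mapping):
        raw = source
    else:
        raw = yaml.safe_load(Path(source).read_text())
    if "parameters" not in raw:
        raise ParameterError("parameter file must contain a 'parameters' section")

    cfg_kwargs = dict(raw.get("config", {}))
    if config_overrides:
        cfg_kwargs.update(config_overrides)
    if "wtp_grid" in cfg_kwargs:
        cfg_kwargs["wtp_grid"] = tuple(float(x) for x in cfg_kwargs["wtp_grid"])
    config = ModelConfig(**cfg_kwargs)

    specs: dict[str, ParameterSpec] = {}
    errors: list[str] = []
    for name, entry in raw["parameters"].items():
        if not isinstance(entry, Mapping):
            entry = {"mean": entry}
        try:
            specs[name] = ParameterSpec(
                name=name,
                mean=float(entry["mean"]),
                se=None if entry.get("se") is None else float(entry["se"]),
                family=entry.get("family", "fixed"),
                units=entry.get("units", ""),
            )
        except (ParameterError, KeyError) as exc:
            errors.append(f"{name}: {exc}")
    if errors:
        raise ParameterError("invalid parameter specs: " + "; ".join(errors))
    ps = ParameterSet(specs=specs, config=config)
    if overrides:
        ps = ps.with_overrides(**overrides)
    return ps
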