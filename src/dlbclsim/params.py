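"""Model parameterisation: decision nodes, unit costs, time-to-event laws,
phase bundles and the life table, with loading, validation and PSA draws.

The packaged defaults come in two layers. ``table_params.yaml`` carries the
published headline parameterisation (decision probabilities with Beta or
Dirichlet hyperparameters, GBP-2013 unit costs, model constants).
``esm_params.yaml`` carries everything the headline tables do not print —
treatment-outcome nodes, regimen mix, time-to-event coefficients, costing
bundles — as flagged, package-calibrated placeholder values. User
configuration files override either layer key-by-key.

Base-case runs use the printed point estimates; the Beta/Dirichlet
hyperparameters only drive probabilistic-sensitivity draws (several printed
proportions differ slightly from the hyperparameter means, so the two are
deliberately kept apart). Degenerate hyperparameters (a zero alpha in a
binary node) act as point masses at 0 or 1.
"""

from __future__ import annotations

import copy
import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .dists import TTEModel, perturb_tte_model, sample_beta, sample_dirichlet

#: transitions the pathway engine must be able to draw times for
REQUIRED_TRANSITIONS = (
    "diagnosis_to_treatment",
    "treatment_line1",
    "treatment_line2",
    "treatment_line2_asct",
    "treatment_line3",
    "first_response_exit",
    "second_response_exit",
    "eol_untreated",
    "eol_treated",
)

REQUIRED_NODES = (
    "sex", "diagnostic_category", "initial_treatment",
    "refractory_line1", "relapse_line1", "refractory_line2", "relapse_line2",
    "refractory_line3", "relapse_line3",
    "outcome_line1", "outcome_line2", "outcome_line3",
    "asct_line2", "exit_type_resp1", "exit_type_resp2",
)


class ConfigurationError(ValueError):
    """Raised when a configuration source cannot be parsed or is incomplete."""


@dataclass
class Band:
    ages: tuple  # [lower, upper) in years
    p: np.ndarray
    alphas: np.ndarray
    provenance: str | None = None


@dataclass
class DecisionNode:
    """An age-banded branch probability with PSA hyperparameters."""

    name: str
    outcome_labels: list
    bands: list

    @classmethod
    def from_dict(cls, name: str, d: dict) -> "DecisionNode":
        bands = [
            Band(tuple(b["ages"]), np.asarray(b["p"], dtype=float),
                 np.asarray(b["alphas"], dtype=float), b.get("provenance"))
            for b in d["bands"]
        ]
        return cls(name=name, outcome_labels=list(d["outcomes"]), bands=bands)

    def to_dict(self) -> dict:
        out = {"outcomes": list(self.outcome_labels), "bands": []}
        for b in self.bands:
            bd = {"ages": list(b.ages), "p": [float(x) for x in b.p],
                  "alphas": [float(x) for x in b.alphas]}
            if b.provenance:
                bd["provenance"] = b.provenance
            out["bands"].append(bd)
        return out

    def band_for(self, age: float) -> Band:
        for b in self.bands:
            if b.ages[0] <= age < b.ages[1]:
                return b
        raise ConfigurationError(
            f"age {age} outside all bands of decision node {self.name!r}")

    def prob_vector(self, age: float) -> np.ndarray:
        return self.band_for(age).p

    def sample_outcome(self, age: float, rng) -> str:
        p = self.prob_vector(age)
        idx = int(rng.choice(len(p), p=p / p.sum()))
        return self.outcome_labels[idx]

    def psa_draw(self, rng) -> "DecisionNode":
        """New node with each band's probabilities drawn from Beta/Dirichlet."""
        new_bands = []
        for b in self.bands:
            if len(b.alphas) == 2:
                p1 = sample_beta(b.alphas[0], b.alphas[1], rng=rng)
                p = np.array([p1, 1.0 - p1])
            else:
                p = sample_dirichlet(b.alphas, rng=rng)
            new_bands.append(Band(b.ages, p, b.alphas, b.provenance))
        return DecisionNode(self.name, self.outcome_labels, new_bands)


class LifeTable:
    """Annual death probabilities qx by single year of age and sex."""

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        frame["age"] = frame["age"].astype(int)
        frame["qx"] = frame["qx"].astype(float)
        self.frame = frame.sort_values(["sex", "age"]).reset_index(drop=True)
        self._qx = {
            sex: g.set_index("age")["qx"] for sex, g in self.frame.groupby("sex")
        }

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def sexes(self):
        return sorted(self._qx)

    def age_range(self) -> tuple:
        ages = self.frame["age"]
        return int(ages.min()), int(ages.max())

    def qx_vector(self, sex: str) -> np.ndarray:
        if sex not in self._qx:
            raise KeyError(f"sex {sex!r} not in life table")
        return self._qx[sex].to_numpy()

    def life_expectancy(self, age: int, sex: str) -> float:
        """Period life expectancy at integer age (half-year death convention)."""
        qx = self.qx_vector(sex)
        lo, hi = self.age_range()
        lx, e = 1.0, 0.0
        for a in range(int(age), hi + 1):
            q = qx[a - lo]
            e += lx * (1.0 - q) + lx * q * 0.5
            lx *= 1.0 - q
        return e

    def validate(self) -> list:
        issues = []
        if ((self.frame["qx"] < 0) | (self.frame["qx"] > 1)).any():
            issues.append("life_table: qx outside [0, 1]")
        for sex, s in self._qx.items():
            ages = s.index.to_numpy()
            if not np.array_equal(ages, np.arange(ages.min(), ages.max() + 1)):
                issues.append(f"life_table[{sex}]: ages not contiguous")
            if s.iloc[-1] < 1.0:
                issues.append(f"life_table[{sex}]: terminal qx must be 1")
        return issues


@dataclass
class ModelParameters:
    """Complete parameter set consumed by the engine, costing and analyses."""

    decision_nodes: dict
    unit_costs: dict
    tte_models: dict
    regimens: dict
    regimen_mix: dict
    phase_bundles: dict
    followup: dict
    life_table: LifeTable
    discount_rate_annual: float = 0.035
    cure_threshold_years: float = 5.0
    max_age_years: float = 100.0
    annual_incident_cases_uk: int = 4880
    psa_iterations: int = 500
    prevalence_burn_in_years: int = 10
    age_beta: tuple = (3.73, 2.32)
    age_range_years: tuple = (18.0, 100.0)
    provenance: dict = field(default_factory=dict)

    def regimen_choices(self, line: int, category: str) -> list:
        key = f"line{min(line, 3)}"
        mix = self.regimen_mix[key]
        return mix.get(category, mix["standard"])

    def unit_cost(self, item: str) -> float:
        try:
            return self.unit_costs[item]
        except KeyError:
            raise KeyError(f"unknown unit-cost item {item!r}") from None

    def to_config_dict(self) -> dict:
        """Full configuration as a plain dict (life table excluded)."""
        return {
            "model": {
                "discount_rate_annual": self.discount_rate_annual,
                "cure_threshold_years": self.cure_threshold_years,
                "max_age_years": self.max_age_years,
                "annual_incident_cases_uk": self.annual_incident_cases_uk,
                "psa_iterations": self.psa_iterations,
                "prevalence_burn_in_years": self.prevalence_burn_in_years,
                "age_distribution": {
                    "beta": list(self.age_beta),
                    "range_years": list(self.age_range_years),
                },
            },
            "decision_nodes": {k: v.to_dict() for k, v in self.decision_nodes.items()},
            "unit_costs": dict(self.unit_costs),
            "tte_models": {
                k: {
                    "family": m.family,
                    "params": [float(p) for p in m.params],
                    **({"vcov": np.asarray(m.vcov).tolist()} if m.vcov is not None else {}),
                }
                for k, m in self.tte_models.items()
            },
            "regimens": dict(self.regimens),
            "regimen_mix": copy.deepcopy(self.regimen_mix),
            "phase_bundles": {
                phase: [{"item": item, "qty": qty} for item, qty in items]
                for phase, items in self.phase_bundles.items()
            },
            "followup": dict(self.followup),
        }


def _packaged(name: str):
    return importlib.resources.files("dlbclsim.data").joinpath(name)


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def _build(config: dict, life_table: LifeTable) -> ModelParameters:
    try:
        model = config["model"]
        nodes = {
            name: DecisionNode.from_dict(name, d)
            for name, d in config["decision_nodes"].items()
        }
        tte = {}
        for name, d in config["tte_models"].items():
            vcov = np.asarray(d["vcov"], dtype=float) if "vcov" in d else None
            tte[name] = TTEModel(family=d["family"], params=tuple(d["params"]),
                                 vcov=vcov)
        bundles = {
            phase: [(it["item"], float(it["qty"])) for it in items]
            for phase, items in config["phase_bundles"].items()
        }
        age_dist = model["age_distribution"]
        return ModelParameters(
            decision_nodes=nodes,
            unit_costs={k: float(v) for k, v in config["unit_costs"].items()},
            tte_models=tte,
            regimens=dict(config["regimens"]),
            regimen_mix=copy.deepcopy(config["regimen_mix"]),
            phase_bundles=bundles,
            followup=dict(config["followup"]),
            life_table=life_table,
            discount_rate_annual=float(model["discount_rate_annual"]),
            cure_threshold_years=float(model["cure_threshold_years"]),
            max_age_years=float(model["max_age_years"]),
            annual_incident_cases_uk=int(model["annual_incident_cases_uk"]),
            psa_iterations=int(model["psa_iterations"]),
            prevalence_burn_in_years=int(model["prevalence_burn_in_years"]),
            age_beta=tuple(age_dist["beta"]),
            age_range_years=tuple(age_dist["range_years"]),
            provenance={"esm_blocks": config.get("provenance", "")},
        )
    except KeyError as exc:
        raise ConfigurationError(f"missing configuration key: {exc}") from exc
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(str(exc)) from exc


def _default_config() -> dict:
    with _packaged("table_params.yaml").open() as fh:
        table = yaml.safe_load(fh)
    with _packaged("esm_params.yaml").open() as fh:
        esm = yaml.safe_load(fh)
    merged = _deep_merge(table, esm)
    return merged


def default_life_table() -> LifeTable:
    """Packaged synthetic national-style life table (see its filename)."""
    with _packaged("life_table_synthetic_uk.csv").open() as fh:
        return LifeTable(pd.read_csv(fh))


def default_parameters() -> ModelParameters:
    """Packaged defaults; raises if they violate their own invariants."""
    params = _build(_default_config(), default_life_table())
    issues = validate_parameters(params)
    if issues:
        raise ConfigurationError("packaged defaults invalid: " + "; ".join(issues))
    return params


def load_parameters(config_source=None, life_table_path=None) -> ModelParameters:
    """Load parameters, overlaying a user config onto the packaged defaults.

    ``config_source`` may be None (pure defaults), a path to a YAML file, or
    an already-parsed dict. The override is merged key-by-key, so a file may
    specify only the blocks it changes.
    """
    base = _default_config()
    if config_source is not None:
        if isinstance(config_source, dict):
            override = config_source
        else:
            try:
                with open(config_source) as fh:
                    override = yaml.safe_load(fh)
            except yaml.YAMLError as exc:
                raise ConfigurationError(f"cannot parse {config_source}: {exc}") from exc
        if override:
            base = _deep_merge(base, override)
    life_table = (LifeTable.from_csv(life_table_path) if life_table_path
                  else default_life_table())
    params = _build(base, life_table)
    issues = validate_parameters(params)
    if issues:
        raise ConfigurationError("invalid configuration: " + "; ".join(issues))
    return params


def save_parameters(params: ModelParameters, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_config_dict(), fh, sort_keys=True)


def validate_parameters(params: ModelParameters) -> list:
    """All invariant violations as human-readable messages; empty iff valid."""
    issues = []
    for name, node in params.decision_nodes.items():
        k = len(node.outcome_labels)
        for b in node.bands:
            where = f"decision_nodes.{name}[{b.ages[0]}-{b.ages[1]})"
            if len(b.p) != k or len(b.alphas) != k:
                issues.append(f"{where}: outcome count mismatch")
                continue
            if np.any(b.p < 0) or np.any(b.p > 1):
                issues.append(f"{where}: probabilities outside [0, 1]")
            elif abs(float(b.p.sum()) - 1.0) > 1e-9:
                issues.append(f"{where}: probabilities sum to {b.p.sum():.6f}")
            if np.any(b.alphas < 0):
                issues.append(f"{where}: negative hyperparameter")
            if b.alphas.sum() == 0:
                issues.append(f"{where}: all-zero hyperparameters")
    for name in REQUIRED_NODES:
        if name not in params.decision_nodes:
            issues.append(f"decision_nodes.{name}: missing")
    for item, cost in params.unit_costs.items():
        if cost < 0:
            issues.append(f"unit_costs.{item}: negative cost {cost}")
    for name in REQUIRED_TRANSITIONS:
        if name not in params.tte_models:
            issues.append(f"tte_models.{name}: missing transition law")
    for phase, items in params.phase_bundles.items():
        for item, qty in items:
            if item not in params.unit_costs:
                issues.append(f"phase_bundles.{phase}: unknown item {item!r}")
            if qty < 0:
                issues.append(f"phase_bundles.{phase}.{item}: negative quantity")
    for line_key, by_cat in params.regimen_mix.items():
        for cat, choices in by_cat.items():
            tot = sum(c["p"] for c in choices)
            if abs(tot - 1.0) > 1e-9:
                issues.append(f"regimen_mix.{line_key}.{cat}: mix sums to {tot}")
            for c in choices:
                if c["regimen"] not in params.regimens:
                    issues.append(
                        f"regimen_mix.{line_key}.{cat}: unknown regimen {c['regimen']!r}")
                csum = sum(c["cycles"].values())
                if abs(csum - 1.0) > 1e-9:
                    issues.append(
                        f"regimen_mix.{line_key}.{cat}.{c['regimen']}: "
                        f"cycle distribution sums to {csum}")
    if not (0.0 <= params.discount_rate_annual < 1.0):
        issues.append("model.discount_rate_annual: outside [0, 1)")
    if params.cure_threshold_years <= 0:
        issues.append("model.cure_threshold_years: must be > 0")
    if not math.isfinite(params.age_beta[0]) or params.age_beta[0] <= 0 \
            or params.age_beta[1] <= 0:
        issues.append("model.age_distribution.beta: shapes must be > 0")
    issues.extend(params.life_table.validate())
    return issues


def draw_psa_parameters(params: ModelParameters, seed) -> ModelParameters:
    """One probabilistic-sensitivity draw of the full parameter set.

    Decision-node probabilities are redrawn from their Beta/Dirichlet
    hyperparameters, time-to-event coefficients from their multivariate
    normal (on the unconstrained scale), and unit costs are held fixed.
    The same seed always produces the same draw. ``seed`` may also be a
    numpy Generator or SeedSequence for stream splitting.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    new = copy.copy(params)
    new.decision_nodes = {
        name: node.psa_draw(rng) for name, node in params.decision_nodes.items()
    }
    new.tte_models = {
        name: perturb_tte_model(model, rng)
        for name, model in params.tte_models.items()
    }
    return new
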