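"""Declarative covariance-structure model specifications.

A :class:`ModelSpec` is a labeled path model over observed and latent
variables: directed paths, (co)variances, and means, each either fixed to a
value or carrying a free-parameter label.  Equality constraints are expressed
by sharing a label.  The engine maps a spec into RAM matrices
(``Sigma = F (I-A)^-1 S (I-A)^-T F^T``, ``mu = F (I-A)^-1 m``).

Free (co)variance entries come in three flavours, recorded per entry:

``var``
    a variance (S diagonal); kept positive by the engine (log transform).
``corr``
    an off-diagonal S entry parameterized as a correlation: the actual
    covariance is ``r * sqrt(S_ii * S_jj)``.  Both endpoint variances must be
    free or fixed S diagonals.  This makes equality constraints on couplings
    act on the standardized scale, as the analysis requires.
``cov``
    a raw, untransformed covariance.

The module also houses the builders for the two latent difference score
models: Model A (total brain volume) and Model B (grey matter,
normal-appearing white matter, and white-matter-hyperintensity volumes).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

from . import schema


class ModelSpecError(ValueError):
    """Schema / identification errors while building a spec."""


@dataclass
class Entry:
    """One path/covariance/mean entry: free (labelled) or fixed."""

    label: str | None = None
    value: float | None = None
    scale: str = "cov"  # for covariance entries: var | corr | cov

    def __post_init__(self) -> None:
        if (self.label is None) == (self.value is None):
            raise ModelSpecError("entry must have exactly one of label/value")

    @property
    def free(self) -> bool:
        return self.label is not None

    def to_dict(self) -> dict:
        d: dict = {"label": self.label} if self.free else {"fixed": self.value}
        if self.scale != "cov":
            d["scale"] = self.scale
        return d

    @staticmethod
    def from_dict(d: Mapping) -> "Entry":
        return Entry(
            label=d.get("label"),
            value=d.get("fixed"),
            scale=d.get("scale", "cov"),
        )


def _ckey(a: str, b: str) -> tuple[str, str]:
    """Symmetric covariance key (canonical order)."""
    return (a, b) if a <= b else (b, a)


@dataclass
class ModelSpec:
    """A labeled path model (directed paths, covariances, means)."""

    name: str = "model"
    variables: list[tuple[str, str]] = field(default_factory=list)  # (name, role)
    paths: dict[tuple[str, str], Entry] = field(default_factory=dict)  # (src, dst)
    covs: dict[tuple[str, str], Entry] = field(default_factory=dict)
    means: dict[str, Entry] = field(default_factory=dict)
    #: per-variable scale anchor used to map results fitted on rescaled data
    #: back to input units; latents anchor on their reference indicator
    scale_anchor: dict[str, str] = field(default_factory=dict)

    # -- construction ------------------------------------------------------
    def add_variable(self, name: str, role: str = "observed") -> None:
        if role not in ("observed", "latent"):
            raise ModelSpecError(f"bad role {role!r}")
        if name in self._varset():
            raise ModelSpecError(f"duplicate variable {name!r}")
        self.variables.append((name, role))

    def _varset(self) -> set[str]:
        return {n for n, _ in self.variables}

    def _check_var(self, name: str) -> None:
        if name not in self._varset():
            raise ModelSpecError(f"unknown variable {name!r}")

    def add_path(self, src: str, dst: str, label: str | None = None,
                 fixed: float | None = None) -> None:
        self._check_var(src)
        self._check_var(dst)
        if (src, dst) in self.paths:
            raise ModelSpecError(f"duplicate path {src} -> {dst}")
        self.paths[(src, dst)] = Entry(label=label, value=fixed)

    def add_cov(self, a: str, b: str, label: str | None = None,
                fixed: float | None = None, scale: str | None = None) -> None:
        self._check_var(a)
        self._check_var(b)
        key = _ckey(a, b)
        if key in self.covs:
            raise ModelSpecError(f"duplicate covariance {key}")
        if scale is None:
            scale = "var" if a == b else "cov"
        if a == b and scale != "var":
            raise ModelSpecError("diagonal entries must have scale 'var'")
        if a != b and scale == "var":
            raise ModelSpecError("off-diagonal entries cannot be 'var'")
        self.covs[key] = Entry(label=label, value=fixed, scale=scale)

    def set_mean(self, var: str, label: str | None = None,
                 fixed: float | None = None) -> None:
        self._check_var(var)
        self.means[var] = Entry(label=label, value=fixed)

    # -- introspection -----------------------------------------------------
    @property
    def observed(self) -> list[str]:
        return [n for n, r in self.variables if r == "observed"]

    @property
    def latents(self) -> list[str]:
        return [n for n, r in self.variables if r == "latent"]

    def _entries(self) -> Iterable[tuple[str, Entry]]:
        for key, e in self.paths.items():
            yield f"path {key[0]}->{key[1]}", e
        for key, e in self.covs.items():
            yield f"cov {key[0]}~~{key[1]}", e
        for var, e in self.means.items():
            yield f"mean {var}", e

    def free_labels(self) -> list[str]:
        """Distinct free-parameter labels, in first-appearance order."""
        seen: dict[str, None] = {}
        for _, e in self._entries():
            if e.free and e.label not in seen:
                seen[e.label] = None
        return list(seen)

    def label_scales(self) -> dict[str, str]:
        """Transform class per label: var / corr / other.

        A label may not mix variance and non-variance uses.
        """
        scales: dict[str, str] = {}
        for where, e in self._entries():
            if not e.free:
                continue
            s = e.scale if where.startswith("cov") else "other"
            if where.startswith("mean") or where.startswith("path"):
                s = "other"
            prev = scales.setdefault(e.label, s)
            if prev != s:
                raise ModelSpecError(
                    f"label {e.label!r} used with incompatible scales "
                    f"({prev} vs {s})"
                )
        return scales

    def n_observed_moments(self) -> int:
        p = len(self.observed)
        return p * (p + 1) // 2 + p

    def validate(self) -> None:
        names = [n for n, _ in self.variables]
        if len(set(names)) != len(names):
            raise ModelSpecError("duplicate variable names")
        for (a, b), e in self.covs.items():
            if e.scale == "corr":
                for v in (a, b):
                    if _ckey(v, v) not in self.covs:
                        raise ModelSpecError(
                            f"correlation-scale entry {a}~~{b} requires a "
                            f"declared variance for {v}"
                        )
        self.label_scales()

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "variables": [{"name": n, "role": r} for n, r in self.variables],
            "paths": [
                {"src": s, "dst": d, **e.to_dict()}
                for (s, d), e in self.paths.items()
            ],
            "covs": [
                {"a": a, "b": b, **e.to_dict()}
                for (a, b), e in self.covs.items()
            ],
            "means": [{"var": v, **e.to_dict()} for v, e in self.means.items()],
            "scale_anchor": dict(self.scale_anchor),
        }

    @staticmethod
    def from_dict(d: Mapping) -> "ModelSpec":
        spec = ModelSpec(name=d.get("name", "model"))
        for v in d["variables"]:
            spec.add_variable(v["name"], v["role"])
        for p in d["paths"]:
            e = Entry.from_dict(p)
            spec.paths[(p["src"], p["dst"])] = e
        for c in d["covs"]:
            e = Entry.from_dict(c)
            spec.covs[_ckey(c["a"], c["b"])] = e
        for m in d["means"]:
            spec.means[m["var"]] = Entry.from_dict(m)
        spec.scale_anchor = dict(d.get("scale_anchor", {}))
        return spec

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @staticmethod
    def from_yaml(text: str) -> "ModelSpec":
        return ModelSpec.from_dict(yaml.safe_load(text))

    def copy(self) -> "ModelSpec":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_measurement_model(
    indicator_map: Mapping[str, Sequence[str]],
    cross_loadings: Sequence[tuple[str, str]] = (),
    invariance: bool = True,
    waves: Sequence[str] = schema.WAVES,
    correlated_uniqueness: bool = True,
    factor_covs: bool = True,
) -> ModelSpec:
    """Two-wave confirmatory factor model with optional strong invariance.

    Each factor's first indicator carries a unit loading; the remaining
    loadings and all indicator intercepts are free.  With ``invariance=True``
    the loadings and intercepts share one label across waves (strong
    measurement invariance); wave-1 factor means are fixed to 0 and later
    waves' factor means are free.  Residual variances are free per wave;
    with ``correlated_uniqueness=True`` each test's residuals covary across
    waves.
    """
    spec = ModelSpec(name="measurement")
    cross_by_test: dict[str, list[str]] = {}
    for test, extra in cross_loadings:
        cross_by_test.setdefault(test, []).append(extra)

    all_tests: list[str] = []
    for factor, tests in indicator_map.items():
        n_ind = len(tests) + sum(
            1 for t, f in cross_loadings if f == factor
        )
        if n_ind < 2:
            raise ModelSpecError(
                f"factor {factor!r} has {n_ind} indicators; not identified"
            )
        for t in tests:
            if t in all_tests:
                raise ModelSpecError(f"test {t!r} assigned to two factors")
        all_tests.extend(tests)
    for test, extra in cross_loadings:
        if test not in all_tests:
            raise ModelSpecError(f"unknown test {test!r} in cross-loadings")
        if extra not in indicator_map:
            raise ModelSpecError(f"unknown factor {extra!r} in cross-loadings")

    for w in waves:
        for t in all_tests:
            spec.add_variable(schema.col(t, w), "observed")
    for w in waves:
        for f in indicator_map:
            spec.add_variable(schema.latent(f, w), "latent")

    def _wave_tag(w: str) -> str:
        return "" if invariance else f"_{w}"

    for w in waves:
        for factor, tests in indicator_map.items():
            fv = schema.latent(factor, w)
            for i, t in enumerate(tests):
                tv = schema.col(t, w)
                if i == 0:
                    spec.add_path(fv, tv, fixed=1.0)
                else:
                    spec.add_path(fv, tv, label=f"lam_{t}{_wave_tag(w)}")
        for test, extra in cross_loadings:
            spec.add_path(
                schema.latent(extra, w), schema.col(test, w),
                label=f"lam_{test}_on_{extra}{_wave_tag(w)}",
            )
        for t in all_tests:
            tv = schema.col(t, w)
            spec.set_mean(tv, label=f"nu_{t}{_wave_tag(w)}")
            spec.add_cov(tv, tv, label=f"theta_{t}_{w}")

    if correlated_uniqueness and len(waves) == 2:
        w1, w2 = waves
        for t in all_tests:
            spec.add_cov(
                schema.col(t, w1), schema.col(t, w2),
                label=f"rtheta_{t}", scale="corr",
            )

    for iw, w in enumerate(waves):
        for f in indicator_map:
            fv = schema.latent(f, w)
            spec.add_cov(fv, fv, label=f"psi_{f}_{w}")
            if iw == 0:
                spec.set_mean(fv, fixed=0.0)
            else:
                spec.set_mean(fv, label=f"alpha_{f}_{w}")
            spec.scale_anchor[fv] = schema.col(indicator_map[f][0], w)

    if factor_covs:
        fvars = [schema.latent(f, w) for w in waves for f in indicator_map]
        for i, a in enumerate(fvars):
            for b in fvars[i + 1:]:
                spec.add_cov(a, b, label=f"r_{a}__{b}", scale="corr")

    spec.validate()
    return spec


def add_latent_change(spec: ModelSpec, var_w1: str, var_w2: str,
                      change_name: str) -> ModelSpec:
    """Decompose ``var_w2 = var_w1 + change`` with a latent change variable.

    Unit-fixed paths from the wave-1 variable and from the change variable
    into the wave-2 variable; the wave-2 variable's residual variance and
    intercept are fixed to 0, so the change IS the wave-2 minus wave-1
    difference.  The change gets a free mean, variance, and correlation with
    the wave-1 level.
    """
    spec = spec.copy()
    for v in (var_w1, var_w2):
        spec._check_var(v)
    if change_name in spec._varset():
        raise ModelSpecError(f"change variable {change_name!r} already exists")
    if (var_w1, var_w2) in spec.paths:
        raise ModelSpecError(
            f"path {var_w1}->{var_w2} already present; "
            f"latent change applied twice?"
        )
    spec.add_variable(change_name, "latent")
    spec.add_path(var_w1, var_w2, fixed=1.0)
    spec.add_path(change_name, var_w2, fixed=1.0)
    # wave-2 variable becomes a deterministic sum
    spec.covs[_ckey(var_w2, var_w2)] = Entry(value=0.0, scale="var")
    spec.means[var_w2] = Entry(value=0.0)
    spec.add_cov(change_name, change_name, label=f"var_{change_name}")
    spec.set_mean(change_name, label=f"alpha_{change_name}")
    spec.add_cov(var_w1, change_name,
                 label=f"r_{var_w1}__{change_name}", scale="corr")
    anchor = spec.scale_anchor.get(var_w1, var_w1)
    spec.scale_anchor[change_name] = anchor
    spec.scale_anchor.setdefault(var_w2, anchor)
    return spec


def build_lds_model(
    volumes: Sequence[str],
    name: str = "lds",
    correlated_uniqueness: bool = True,
    indicator_map: Mapping[str, Sequence[str]] | None = None,
    cross_loadings: Sequence[tuple[str, str]] = None,
) -> ModelSpec:
    """Two-wave latent difference score model: latent cognitive domains
    (measured by their tests at both waves) plus manifest brain volumes,
    every level and change freely intercorrelated on the correlation
    metric."""
    if indicator_map is None:
        indicator_map = schema.FACTOR_TESTS
    if cross_loadings is None:
        cross_loadings = (
            schema.CROSS_LOADINGS
            if indicator_map is schema.FACTOR_TESTS else ()
        )
    factors = list(indicator_map)
    spec = build_measurement_model(
        indicator_map,
        cross_loadings=cross_loadings,
        invariance=True,
        correlated_uniqueness=correlated_uniqueness,
        factor_covs=False,
    )
    spec.name = name
    w1, w2 = schema.WAVES
    # manifest brain volumes, one measurement per wave
    for v in volumes:
        for w in schema.WAVES:
            spec.add_variable(schema.col(v, w), "observed")
        spec.add_cov(schema.col(v, w1), schema.col(v, w1),
                     label=f"var_{v}_{w1}")
        spec.set_mean(schema.col(v, w1), label=f"mu_{v}_{w1}")
        spec.add_cov(schema.col(v, w2), schema.col(v, w2),
                     label=f"var_{v}_{w2}")
        spec.set_mean(schema.col(v, w2), label=f"mu_{v}_{w2}")

    # latent changes: cognitive factors (latent pair) and volumes (manifest)
    for f in factors:
        spec = add_latent_change(
            spec, schema.latent(f, w1), schema.latent(f, w2),
            schema.change(f),
        )
        # wave-2 factor mean/variance already freed by the measurement
        # builder; the change construction re-fixes them to 0.
        spec.means[schema.latent(f, w2)] = Entry(value=0.0)
        spec.covs[_ckey(schema.latent(f, w2), schema.latent(f, w2))] = Entry(
            value=0.0, scale="var"
        )
    for v in volumes:
        spec = add_latent_change(
            spec, schema.col(v, w1), schema.col(v, w2), schema.change(v),
        )

    # all levels and changes freely intercorrelated (correlation scale);
    # the within-variable level-change entries were added by
    # add_latent_change already.
    levels = [schema.latent(f, w1) for f in factors]
    levels += [schema.col(v, w1) for v in volumes]
    changes = [schema.change(f) for f in factors]
    changes += [schema.change(v) for v in volumes]
    everything = levels + changes
    for i, a in enumerate(everything):
        for b in everything[i + 1:]:
            if _ckey(a, b) in spec.covs:
                continue
            spec.add_cov(a, b, label=f"r_{a}__{b}", scale="corr")
    spec.validate()
    return spec


def build_model_a(correlated_uniqueness: bool = True) -> ModelSpec:
    """Model A: three cognitive domains + total brain volume (26 observed)."""
    return build_lds_model(schema.MODEL_A_VOLUMES, "model_A",
                           correlated_uniqueness)


def build_model_b(correlated_uniqueness: bool = True) -> ModelSpec:
    """Model B: three cognitive domains + GM, NAWM, WMH volumes
    (30 observed)."""
    return build_lds_model(schema.MODEL_B_VOLUMES, "model_B",
                           correlated_uniqueness)


def constrain_equal(spec: ModelSpec, labels: Sequence[str]) -> ModelSpec:
    """Return a spec in which the named free parameters share one label.

    Reduces the free-parameter count by ``len(labels) - 1``; constraining a
    label to itself is a no-op.
    """
    labels = list(labels)
    known = set(spec.free_labels())
    for lab in labels:
        if lab not in known:
            raise ModelSpecError(f"unknown or fixed parameter label {lab!r}")
    scales = spec.label_scales()
    if len({scales[lab] for lab in labels}) > 1:
        raise ModelSpecError(
            "cannot equate parameters of different scales: "
            + ", ".join(f"{lab}({scales[lab]})" for lab in labels)
        )
    spec = spec.copy()
    target = labels[0]
    rename = {lab: target for lab in labels[1:]}
    for coll in (spec.paths, spec.covs):
        for e in coll.values():
            if e.free and e.label in rename:
                e.label = rename[e.label]
    for e in spec.means.values():
        if e.free and e.label in rename:
            e.label = rename[e.label]
    return spec


def degrees_of_freedom(spec: ModelSpec) -> int:
    """Observed moments (including means) minus distinct free parameters."""
    df = spec.n_observed_moments() - len(spec.free_labels())
    if df < 0:
        raise ModelSpecError(
            f"model under-identified: {-df} more free parameters than moments"
        )
    return df


#: degrees of freedom reported for the original two-wave cohort analysis this
#: package emulates; our constructions are audited against these (the exact
#: free-parameter inventory behind them is not published, so an exact match
#: is not guaranteed and any discrepancy is reported, not hidden)
REFERENCE_DF = {"A": 276, "B": 348}
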