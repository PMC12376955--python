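"""Demographic model menu, composite likelihood, fitting, AIC comparison.

Models are defined by a builder mapping free parameters to a
:class:`~popdemog.coalsim.DemographyConfig` (times in units of 4 N_ref
generations, sizes relative to N_ref; see the coalsim module conventions).
Expected spectra per unit theta come from the Monte-Carlo engine with common
random numbers, so the likelihood surface is a deterministic function of the
parameters for a fixed engine seed.

The fit criterion is the Poisson composite likelihood used with SFS data:
entry ``d`` of the observed spectrum is Poisson with mean ``theta * m``
where ``m`` is the model spectrum per unit theta, and theta is profiled out
analytically (``theta_hat = sum(d) / sum(m)`` over unmasked entries).
Model ranking uses ``AIC = 2 k - 2 log L``.
"""

from __future__ import annotations

import dataclasses
import hashlib

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import optimize
from .coalsim import DemographyConfig, expected_sfs_mc
from .sfs_builder import Spectrum, fold

__all__ = [
    "ModelSpec",
    "ModelFit",
    "EngineConfig",
    "model_menu",
    "get_model",
    "expected_sfs",
    "fit_model",
    "compare_models",
    "poisson_ll",
]

# default parameter bounds (log-uniform geometry)
_NU = (0.01, 100.0)
_T = (0.001, 10.0)
_M = (1e-3, 20.0)


@dataclasses.dataclass
class EngineConfig:
    """Monte-Carlo expected-SFS engine settings (replicates, CRN seed)."""

    reps_1d: int = 50_000
    reps_2d: int = 10_000
    seed_base: int = 77_000

    def reps(self, dims: int) -> int:
        return self.reps_1d if dims == 1 else self.reps_2d


@dataclasses.dataclass
class ModelSpec:
    """A named demographic model with defaults, bounds, and a config builder."""

    name: str
    dims: int
    param_names: tuple[str, ...]
    defaults: tuple[float, ...]
    bounds: tuple[tuple[float, float], ...]
    builder: object  # callable(params) -> DemographyConfig

    @property
    def k(self) -> int:
        return len(self.param_names)

    def build(self, params) -> DemographyConfig:
        params = tuple(float(p) for p in params)
        if len(params) != self.k:
            raise ValueError(f"{self.name} expects {self.k} parameters")
        return self.builder(*params)


@dataclasses.dataclass
class ModelFit:
    """Result of fitting one model to one spectrum."""

    model: str
    k: int
    params: tuple[float, ...]
    log_likelihood: float
    theta_hat: float
    aic: float
    trace: list
    data_hash: str


# ---------------------------------------------------------------------------
# Model builders.  1D histories are (start_time, nu) epoch lists, most recent
# first, with the ancestral size fixed at 1 (sizes are relative to N_ref).
# ---------------------------------------------------------------------------


def _snm() -> DemographyConfig:
    return DemographyConfig(npops=1, epochs=((0.0, 1.0),))


def _two_epoch(nu: float, T: float) -> DemographyConfig:
    return DemographyConfig(npops=1, epochs=((0.0, nu), (T, 1.0)))


def _three_epoch(nuB: float, nuF: float, TB: float, TF: float) -> DemographyConfig:
    return DemographyConfig(
        npops=1, epochs=((0.0, nuF), (TF, nuB), (TF + TB, 1.0))
    )


def _split_nomig(nu1: float, nu2: float, T: float) -> DemographyConfig:
    return DemographyConfig(
        npops=2,
        epochs=(((0.0, nu1), (T, 1.0)), ((0.0, nu2),)),
        split_time=T,
    )


def _split_symmig(nu1: float, nu2: float, m: float, T: float) -> DemographyConfig:
    return DemographyConfig(
        npops=2,
        epochs=(((0.0, nu1), (T, 1.0)), ((0.0, nu2),)),
        split_time=T,
        migration=((0.0, m, m),),
    )


def _split_asymmig(
    nu1: float, nu2: float, m12: float, m21: float, T: float
) -> DemographyConfig:
    return DemographyConfig(
        npops=2,
        epochs=(((0.0, nu1), (T, 1.0)), ((0.0, nu2),)),
        split_time=T,
        migration=((0.0, m12, m21),),
    )


def _anc_mig(nu1: float, nu2: float, m: float, T1: float, T2: float) -> DemographyConfig:
    # gene flow only during the first T1 after the split; isolation for the
    # most recent T2 (backwards: migration on [T2, T1 + T2))
    return DemographyConfig(
        npops=2,
        epochs=(((0.0, nu1), (T1 + T2, 1.0)), ((0.0, nu2),)),
        split_time=T1 + T2,
        migration=((0.0, 0.0, 0.0), (T2, m, m)),
    )


def _sec_contact(
    nu1: float, nu2: float, m: float, T1: float, T2: float
) -> DemographyConfig:
    # isolation for the first T1 after the split, then secondary contact with
    # gene flow during the most recent T2 (backwards: migration on [0, T2))
    return DemographyConfig(
        npops=2,
        epochs=(((0.0, nu1), (T1 + T2, 1.0)), ((0.0, nu2),)),
        split_time=T1 + T2,
        migration=((0.0, m, m), (T2, 0.0, 0.0)),
    )


def _split_nomig_size(
    nu1a: float, nu2a: float, nu1b: float, nu2b: float, T1: float, T2: float
) -> DemographyConfig:
    # split T1+T2 ago at sizes (nu1a, nu2a); size change to (nu1b, nu2b) T2 ago
    return DemographyConfig(
        npops=2,
        epochs=(
            ((0.0, nu1b), (T2, nu1a), (T1 + T2, 1.0)),
            ((0.0, nu2b), (T2, nu2a)),
        ),
        split_time=T1 + T2,
    )


def _split_symmig_size(
    nu1a: float, nu2a: float, nu1b: float, nu2b: float, m: float,
    T1: float, T2: float
) -> DemographyConfig:
    return DemographyConfig(
        npops=2,
        epochs=(
            ((0.0, nu1b), (T2, nu1a), (T1 + T2, 1.0)),
            ((0.0, nu2b), (T2, nu2a)),
        ),
        split_time=T1 + T2,
        migration=((0.0, m, m),),
    )


def model_menu() -> list[ModelSpec]:
    """The 1D and 2D demographic model families.

    1D: standard neutral model (k=0), two-epoch size change, three-epoch
    (bottleneck/recovery style).  2D: divergence with/without symmetric or
    asymmetric gene flow, ancient migration, secondary contact, and
    size-change variants of the isolation and symmetric-migration models.
    """
    nu, t, mm = _NU, _T, _M
    return [
        ModelSpec("snm", 1, (), (), (), lambda: _snm()),
        ModelSpec("two_epoch", 1, ("nu", "T"), (1.0, 0.5), (nu, t), _two_epoch),
        ModelSpec("three_epoch", 1, ("nuB", "nuF", "TB", "TF"),
                  (1.0, 1.0, 0.3, 0.3), (nu, nu, t, t), _three_epoch),
        ModelSpec("split_nomig", 2, ("nu1", "nu2", "T"), (1.0, 1.0, 0.5),
                  (nu, nu, t), _split_nomig),
        ModelSpec("split_symmig", 2, ("nu1", "nu2", "m", "T"),
                  (1.0, 1.0, 0.5, 0.5), (nu, nu, mm, t), _split_symmig),
        ModelSpec("split_asymmig", 2, ("nu1", "nu2", "m12", "m21", "T"),
                  (1.0, 1.0, 0.5, 0.5, 0.5), (nu, nu, mm, mm, t), _split_asymmig),
        ModelSpec("anc_mig", 2, ("nu1", "nu2", "m", "T1", "T2"),
                  (1.0, 1.0, 0.5, 0.3, 0.3), (nu, nu, mm, t, t), _anc_mig),
        ModelSpec("sec_contact", 2, ("nu1", "nu2", "m", "T1", "T2"),
                  (1.0, 1.0, 0.5, 0.3, 0.3), (nu, nu, mm, t, t), _sec_contact),
        ModelSpec("split_nomig_size", 2,
                  ("nu1a", "nu2a", "nu1b", "nu2b", "T1", "T2"),
                  (1.0, 1.0, 1.0, 1.0, 0.3, 0.3), (nu, nu, nu, nu, t, t),
                  _split_nomig_size),
        ModelSpec("split_symmig_size", 2,
                  ("nu1a", "nu2a", "nu1b", "nu2b", "m", "T1", "T2"),
                  (1.0, 1.0, 1.0, 1.0, 0.5, 0.3, 0.3),
                  (nu, nu, nu, nu, mm, t, t), _split_symmig_size),
    ]


def get_model(name: str) -> ModelSpec:
    for spec in model_menu():
        if spec.name == name:
            return spec
    raise KeyError(f"unknown model {name!r}")


# ---------------------------------------------------------------------------
# Expected spectra and likelihood
# ---------------------------------------------------------------------------


def expected_sfs(
    model: ModelSpec,
    params,
    n_alleles: tuple[int, ...],
    engine: EngineConfig,
) -> Spectrum:
    """Folded, corner-masked expected spectrum per unit theta (CRN engine)."""
    cfg = model.build(params)
    reps = engine.reps(model.dims)
    raw = expected_sfs_mc(cfg, n_alleles if model.dims == 2 else n_alleles[0],
                          reps, engine.seed_base)
    if model.dims == 1:
        n = n_alleles[0]
        counts = np.zeros(n + 1)
        counts[1:n] = raw
        spec = Spectrum(counts, (n,))
    else:
        spec = Spectrum(raw, tuple(n_alleles))
    return fold(spec).mask_corners()


def poisson_ll(data: Spectrum, model_per_theta: Spectrum) -> tuple[float, float]:
    """Profiled Poisson composite log-likelihood; returns (logL, theta_hat).

    theta_hat = sum(d)/sum(m) over jointly unmasked entries, then
    ``logL = sum d ln(theta m) - theta m - ln Gamma(d + 1)``.  Model entries
    are floored at a tiny positive value so finite-replicate Monte-Carlo
    zeros cannot produce infinite penalties.
    """
    if data.counts.shape != model_per_theta.counts.shape:
        raise ValueError("data and model spectra have different shapes")
    use = ~(data.mask | model_per_theta.mask)
    d = data.counts[use]
    m = np.maximum(model_per_theta.counts[use], 1e-12)
    theta_hat = float(d.sum() / m.sum())
    mu = theta_hat * m
    ll = float((d * np.log(mu) - mu - gammaln(d + 1)).sum())
    return ll, theta_hat


def _hash_spectrum(s: Spectrum) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(s.counts).tobytes())
    h.update(np.ascontiguousarray(s.mask).tobytes())
    return h.hexdigest()[:16]


def fit_model(
    data: Spectrum,
    model: ModelSpec,
    engine: EngineConfig | None = None,
    seed: int | None = None,
    rounds=optimize.DEFAULT_ROUNDS,
) -> ModelFit:
    """Fit one model to a folded spectrum with the three-round protocol.

    The parameter-free standard neutral model is evaluated directly (there
    is nothing to optimize).  ``AIC = 2 k - 2 logL``.
    """
    engine = engine or EngineConfig()
    if not data.folded:
        raise ValueError("fit folded spectra")
    n_alleles = data.sample_sizes
    if (model.dims == 1) != (data.dims == 1):
        raise ValueError("model and data dimensionality differ")

    def neg_ll(params) -> float:
        try:
            spec = expected_sfs(model, params, n_alleles, engine)
        except ValueError:
            return np.inf
        ll, _ = poisson_ll(data, spec)
        return -ll

    if model.k == 0:
        spec = expected_sfs(model, (), n_alleles, engine)
        ll, theta = poisson_ll(data, spec)
        return ModelFit(model.name, 0, (), ll, theta, -2.0 * ll, [],
                        _hash_spectrum(data))
    best, val, trace = optimize.three_round_protocol(
        neg_ll, np.array(model.defaults), list(model.bounds), seed=seed,
        rounds=rounds,
    )
    spec = expected_sfs(model, best, n_alleles, engine)
    ll, theta = poisson_ll(data, spec)
    return ModelFit(model.name, model.k, tuple(best), ll, theta,
                    2.0 * model.k - 2.0 * ll, trace, _hash_spectrum(data))


def compare_models(fits: list[ModelFit]) -> pd.DataFrame:
    """Rank fits of the same spectrum by AIC (ascending) with delta-AIC."""
    if not fits:
        raise ValueError("no fits to compare")
    hashes = {f.data_hash for f in fits}
    if len(hashes) > 1:
        raise ValueError("fits computed on different data spectra")
    rows = [
        {
            "model": f.model,
            "k": f.k,
            "log_likelihood": f.log_likelihood,
            "theta_hat": f.theta_hat,
            "aic": f.aic,
            "params": f.params,
        }
        for f in fits
    ]
    df = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    df["best"] = df["delta_aic"] == 0.0
    return df
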