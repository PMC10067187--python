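"""Synthetic OTU tables with per-class, per-feature negative-binomial structure.

Amplicon-derived OTU count tables are overdispersed relative to Poisson, and
the negative binomial is the standard model for them.  The generator here
fits an independent NB to every (class, feature) pair of a real table
(method of moments) or takes a fully parametric specification, then draws
independent counts.  The parameterisation is (mean mu, size r) with
``var = mu + mu**2 / r``; large r approaches Poisson.

Fidelity limits: features are generated independently (no cross-feature
correlation, no compositional constraint, no zero-inflation beyond what the
NB itself produces).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io import HEALTHY, SICK, OTUTable, ValidationError

__all__ = [
    "NBSpec",
    "fit_nb_per_class",
    "generate",
    "make_separable_fixture",
    "separable_nb_params",
    "POISSON_SENTINEL",
]

#: dispersion assigned when a feature is under-dispersed (s^2 <= mean);
#: at this size the NB is numerically Poisson.
POISSON_SENTINEL = 1e8


@dataclass
class NBSpec:
    """Per-class, per-feature negative-binomial specification.

    ``mu_healthy``/``mu_sick`` are mean vectors (length f, >= 0) and
    ``r_healthy``/``r_sick`` the matching size parameters (> 0) under
    ``var = mu + mu**2 / r``.
    """

    mu_healthy: np.ndarray
    r_healthy: np.ndarray
    mu_sick: np.ndarray
    r_sick: np.ndarray
    n_healthy: int
    n_sick: int
    seed: int = 0
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        for name in ("mu_healthy", "r_healthy", "mu_sick", "r_sick"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        f = self.mu_healthy.shape[0]
        if not all(
            getattr(self, v).shape == (f,) for v in ("r_healthy", "mu_sick", "r_sick")
        ):
            raise ValidationError("NBSpec vectors must share one length f")
        if np.any(self.mu_healthy < 0) or np.any(self.mu_sick < 0):
            raise ValidationError("NB means must be >= 0")
        if np.any(self.r_healthy <= 0) or np.any(self.r_sick <= 0):
            raise ValidationError("NB sizes must be > 0")
        if not np.all(np.isfinite(self.mu_healthy)) or not np.all(np.isfinite(self.mu_sick)):
            raise ValidationError("NB means must be finite")
        if self.n_healthy + self.n_sick < 2:
            raise ValidationError("need n_healthy + n_sick >= 2")

    @property
    def n_features(self) -> int:
        return self.mu_healthy.shape[0]

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "mu_healthy": self.mu_healthy.tolist(),
            "r_healthy": self.r_healthy.tolist(),
            "mu_sick": self.mu_sick.tolist(),
            "r_sick": self.r_sick.tolist(),
            "n_healthy": int(self.n_healthy),
            "n_sick": int(self.n_sick),
            "seed": int(self.seed),
            "feature_names": self.feature_names,
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NBSpec":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _moments_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments (mu, r) per column; under-dispersed columns get the
    Poisson sentinel size."""
    mu = x.mean(axis=0)
    s2 = x.var(axis=0, ddof=1)
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(s2))):
        raise ValidationError("non-finite sample moments")
    r = np.full_like(mu, POISSON_SENTINEL)
    over = s2 > mu
    r[over] = mu[over] ** 2 / (s2[over] - mu[over])
    # guard against astronomically large but finite ratios
    np.clip(r, None, POISSON_SENTINEL, out=r)
    return mu, r


def fit_nb_per_class(table: OTUTable, seed: int = 0) -> NBSpec:
    """Fit an independent NB to each (class, feature) pair by method of moments.

    mu-hat is the sample mean; r-hat = mu^2 / (s^2 - mu) from the variance
    identity; features with s^2 <= mu fall back to an effectively Poisson
    size of 1e8.  Each class needs at least two samples.
    """
    healthy = table.features[table.labels == HEALTHY]
    sick = table.features[table.labels == SICK]
    for name, x in (("healthy", healthy), ("sick", sick)):
        if x.shape[0] < 2:
            raise ValidationError(f"class {name!r} needs >= 2 samples to fit, got {x.shape[0]}")
    mu_h, r_h = _moments_fit(healthy)
    mu_s, r_s = _moments_fit(sick)
    return NBSpec(
        mu_healthy=mu_h,
        r_healthy=r_h,
        mu_sick=mu_s,
        r_sick=r_s,
        n_healthy=healthy.shape[0],
        n_sick=sick.shape[0],
        seed=seed,
        feature_names=list(table.feature_names),
    )


def _draw_class(rng: np.random.Generator, mu: np.ndarray, r: np.ndarray, n: int) -> np.ndarray:
    if n == 0:
        return np.zeros((0, mu.shape[0]))
    # numpy's negative_binomial(n=r, p) has mean r(1-p)/p; p = r/(r+mu) gives mean mu.
    p = r / (r + mu)
    out = np.zeros((n, mu.shape[0]), dtype=float)
    positive = mu > 0
    if positive.any():
        out[:, positive] = rng.negative_binomial(
            r[positive], p[positive], size=(n, int(positive.sum()))
        )
    return out


def generate(spec: NBSpec) -> OTUTable:
    """Draw an OTU table from an :class:`NBSpec`.

    Healthy rows come first, then sick rows; class counts match the spec
    exactly and the draw is deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    healthy = _draw_class(rng, spec.mu_healthy, spec.r_healthy, spec.n_healthy)
    sick = _draw_class(rng, spec.mu_sick, spec.r_sick, spec.n_sick)
    features = np.vstack([healthy, sick])
    labels = np.concatenate(
        [np.full(spec.n_healthy, HEALTHY, dtype=int), np.full(spec.n_sick, SICK, dtype=int)]
    )
    names = spec.feature_names or [f"OTU{j:04d}" for j in range(spec.n_features)]
    ids = [f"S{i:05d}" for i in range(spec.n_healthy + spec.n_sick)]
    return OTUTable(sample_ids=ids, features=features, feature_names=list(names), labels=labels)


def separable_nb_params(
    f: int,
    effect: float,
    seed: int,
    frac_informative: float = 0.2,
    base_mean_range: tuple[float, float] = (5.0, 40.0),
    dispersion: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-class (mu, r) vectors for a two-class parametric fixture.

    A fraction of features (default 20%) are informative: their sick-class
    mean is ``effect`` times the healthy-class mean.  The rest share means.
    Baseline means are uniform on ``base_mean_range``; all features share
    one NB size (default 2, a strongly overdispersed, microbiome-typical
    value).
    """
    if effect <= 0:
        raise ValidationError("effect must be > 0")
    if f < 2:
        raise ValidationError("need f >= 2 features")
    rng = np.random.default_rng(seed)
    mu_h = rng.uniform(*base_mean_range, size=f)
    mu_s = mu_h.copy()
    n_info = max(1, int(round(frac_informative * f)))
    informative = rng.choice(f, size=n_info, replace=False)
    mu_s[informative] = effect * mu_h[informative]
    r = np.full(f, dispersion)
    return mu_h, r.copy(), mu_s, r.copy()


def make_separable_fixture(
    n_per_class: int,
    f: int,
    effect: float,
    seed: int,
    frac_informative: float = 0.2,
    n_healthy: int | None = None,
    n_sick: int | None = None,
) -> OTUTable:
    """Two-class NB fixture with a multiplicative class effect on 20% of features.

    ``effect=1`` makes the classes exchangeable; large effects (e.g. 8) make
    them separable by a nearest-centroid rule.  ``n_healthy``/``n_sick``
    override the symmetric ``n_per_class`` to build imbalanced fixtures.
    """
    if n_per_class < 10:
        raise ValidationError("n_per_class must be >= 10")
    mu_h, r_h, mu_s, r_s = separable_nb_params(f, effect, seed, frac_informative)
    spec = NBSpec(
        mu_healthy=mu_h,
        r_healthy=r_h,
        mu_sick=mu_s,
        r_sick=r_s,
        n_healthy=n_per_class if n_healthy is None else n_healthy,
        n_sick=n_per_class if n_sick is None else n_sick,
        seed=seed,
    )
    return generate(spec)
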