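"""Synthetic nutrient/response generators for the four benchmark models.

Each dataset has ``d`` nutrient columns: columns 1..d-1 are iid N(0, 1) and
column d is a composition fraction |X1| / (|X1| + |X2|) + r*eps, mimicking
nutrient-proportion covariates (e.g. protein:carbohydrate ratios) common in
nutritional geometry.  The response depends non-linearly on a small
informative subset that always includes the composition column:

    Model 1:  G = exp{-(X1^2 + Xd^2)} + r*eps                  informative {1, d}
    Model 2:  G = sin{(pi/2)(X1^2 + Xd^2)} + r*eps             informative {1, d}
    Model 3:  G = exp{-(X1^2 + |X3|)/5} + exp{-Xd^2/5} + r*eps informative {1, 3, d}
    Model 4:  G = exp{-(X1^2 + X2^2)/2}
              + exp{-(X3^2 + Xd^2)/2} + r*eps                  informative {1, 2, 3, d}

with eps ~ N(0, 1) drawn independently for the composition column and the
response, and r the noise level.  Default study conditions: n in {20, 50, 100},
d in {10, 20}, r in {0.05, 0.1, 0.2}.

Because the method always z-scores nutrient columns before computing LC, the
response is built from the *standardized* columns: each column is centred and
scaled by its sample mean and SD, and the model formula is evaluated on those
standardized values.  This puts the composition fraction on the same scale as
the iid columns and makes it symmetric about 0, so the even model functions
carry no linear signal through it — the regime in which a linear F-test is
expected to be nearly blind while a local-smoothness statistic is not.  The
returned ``X`` keeps the raw units (iid N(0,1) columns, composition in [0,1]
plus noise); consumers standardize before computing LC, which reproduces
exactly the values the response was built from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate_dataset", "null_pair",
           "INFORMATIVE_SETS"]


def _informative(model: int, d: int) -> tuple[int, ...]:
    # 0-based indices; column d-1 is the composition fraction
    return {
        1: (0, d - 1),
        2: (0, d - 1),
        3: (0, 2, d - 1),
        4: (0, 1, 2, d - 1),
    }[model]


INFORMATIVE_SETS = _informative


@dataclass
class SimulationConfig:
    """Settings of one synthetic dataset draw."""

    model: int
    n: int = 100
    d: int = 10  # total columns incl. the composition fraction
    r: float = 0.1
    seed: int | None = None

    def __post_init__(self):
        if self.model not in (1, 2, 3, 4):
            raise ValueError(f"model must be in 1..4, got {self.model}")
        min_d = 4 if self.model in (3, 4) else 3
        if self.d < min_d:
            raise ValueError(f"model {self.model} needs d >= {min_d}")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.r < 0:
            raise ValueError("noise level r must be >= 0")


@dataclass
class SimulatedDataset:
    X: np.ndarray  # (n, d)
    G: np.ndarray  # (n,)
    informative_set: tuple[int, ...]  # 0-based column indices
    column_names: list[str] = field(default_factory=list)


def simulate_dataset(cfg: SimulationConfig,
                     rng: np.random.Generator | None = None) -> SimulatedDataset:
    """Draw one dataset from the configured generating model."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n, d, r = cfg.n, cfg.d, cfg.r
    Z = rng.standard_normal((n, d - 1))
    comp = np.abs(Z[:, 0]) / (np.abs(Z[:, 0]) + np.abs(Z[:, 1]))
    comp = comp + r * rng.standard_normal(n)
    X = np.column_stack([Z, comp])
    # response is smooth over the standardized nutrient space (see module doc)
    Xz = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    x1, x2, x3, xd = Xz[:, 0], Xz[:, 1], Xz[:, 2], Xz[:, -1]
    if cfg.model == 1:
        signal = np.exp(-(x1**2 + xd**2))
    elif cfg.model == 2:
        signal = np.sin((np.pi / 2) * (x1**2 + xd**2))
    elif cfg.model == 3:
        signal = np.exp(-(x1**2 + np.abs(x3)) / 5) + np.exp(-(xd**2) / 5)
    else:
        signal = np.exp(-(x1**2 + x2**2) / 2) + np.exp(-(x3**2 + xd**2) / 2)
    G = signal + r * rng.standard_normal(n)
    names = [f"X{i + 1}" for i in range(d)]
    return SimulatedDataset(X=X, G=G, informative_set=_informative(cfg.model, d),
                            column_names=names)


def null_pair(cfg: SimulationConfig, k: int = 2, seed: int | None = None,
              rng: np.random.Generator | None = None) -> tuple[int, ...]:
    """A uniformly random k-subset of the non-informative columns.

    By construction the response carries no signal over these columns, so
    tests run on the returned subset estimate the false-positive rate.
    """
    informative = set(_informative(cfg.model, cfg.d))
    pool = [c for c in range(cfg.d) if c not in informative]
    if len(pool) < k:
        raise ValueError(
            f"only {len(pool)} non-informative columns available, need {k}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    return tuple(sorted(int(c) for c in rng.choice(pool, size=k, replace=False)))
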