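"""Box-Cox symmetrisation and standardisation of landscape metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["TransformSpec", "boxcox_standardize"]


@dataclass
class TransformSpec:
    lmbda: float
    shift: float
    mean: float
    sd: float

    def apply(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float) + self.shift
        if abs(self.lmbda) < 1e-12:
            t = np.log(x)
        else:
            t = (x ** self.lmbda - 1.0) / self.lmbda
        return (t - self.mean) / self.sd


def boxcox_standardize(
    x, grid=(-2.0, 2.0), step: float = 0.05
) -> tuple[np.ndarray, TransformSpec]:
    """Box-Cox transform (grid-search lambda) followed by center/scale.

    The shift 1 - min(x) is applied when the minimum is non-positive so the
    transform is defined; lambda maximises the Box-Cox normal log-likelihood
    on a [-2, 2] grid with step 0.05.  Output has mean 0 and sd 1 on the
    fitting sample.  A constant vector raises (the metric is dropped and
    logged by the caller).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant vector cannot be transformed")
    shift = 1.0 - x.min() if x.min() <= 0 else 0.0
    xs = x + shift
    lambdas = np.arange(grid[0], grid[1] + step / 2, step)
    llf = np.array([stats.boxcox_llf(l, xs) for l in lambdas])
    lmbda = float(lambdas[np.argmax(llf)])
    if abs(lmbda) < 1e-12:
        t = np.log(xs)
    else:
        t = (xs ** lmbda - 1.0) / lmbda
    mean = float(t.mean())
    sd = float(t.std(ddof=0))
    if sd == 0:
        raise ValueError("transformed vector is constant")
    return (t - mean) / sd, TransformSpec(lmbda, shift, mean, sd)
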