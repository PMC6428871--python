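"""Cross-layer redundancy: predicting higher-layer degrees from LD_1.

For each clone the exact-layer degrees form a profile across LD_1..max_ld.
Redundancy of the layered architecture is scored by how well a simple linear
regression on the LD_1 degree predicts each higher layer's degree, measured
out-of-sample by leave-one-out cross-validation:

    Q^2 = (1 - PRESS / TSS) * 100

with PRESS the predictive error sum of squares over the n leave-one-out
refits and TSS the total sum of squares of the response.  Q^2 = 100 means
perfect prediction; Q^2 <= 0 means the regression predicts no better than
the response mean.  The LOOCV residuals are obtained through the exact
leverage identity e_[j] = e_j / (1 - h_jj), which equals the literal n-fold
refit for least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distance import LayeredNetwork, layer_degrees


@dataclass(frozen=True)
class LoocvResult:
    q2: float | None      # percent; None when undefined (constant response)
    press: float
    tss: float
    n: int


@dataclass
class RedundancyResult:
    """Q^2 of LD_1 predicting each target layer of one sample."""

    sample_id: str
    predictor_layer: int
    per_layer: dict[int, LoocvResult | None] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m, res in sorted(self.per_layer.items()):
            rows.append(
                {
                    "sample_id": self.sample_id,
                    "predictor_layer": self.predictor_layer,
                    "target_layer": m,
                    "q2": res.q2 if res else None,
                    "press": res.press if res else None,
                    "tss": res.tss if res else None,
                    "n_clones": res.n if res else None,
                }
            )
        return pd.DataFrame(rows)


def layer_degree_matrix(net: LayeredNetwork) -> np.ndarray:
    """(n_clones, max_ld) matrix; column n-1 holds exact-layer-n degrees.

    Zero degrees are kept: the regression operates on full clone-aligned
    vectors.
    """
    cols = [layer_degrees(net, n, "exact") for n in range(1, net.max_ld + 1)]
    return np.column_stack(cols)


def loocv_q2(x, y) -> LoocvResult:
    """Leave-one-out cross-validated Q^2 for the simple linear model
    y = b0 + b1 x.

    Uses the closed-form leverage shortcut (identical to literally refitting
    the model n times with one case deleted).  A constant predictor reduces
    to the intercept-only model (prediction = leave-one-out mean).  A
    constant response has TSS = 0 and Q^2 is undefined (None).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("LOOCV Q^2 requires at least 3 observations")
    tss = float(((y - y.mean()) ** 2).sum())
    xc = x - x.mean()
    sxx = float((xc**2).sum())
    if sxx == 0:
        # intercept-only model
        h = np.full(n, 1.0 / n)
        resid = y - y.mean()
    else:
        beta1 = float((xc * (y - y.mean())).sum() / sxx)
        beta0 = float(y.mean() - beta1 * x.mean())
        resid = y - (beta0 + beta1 * x)
        h = 1.0 / n + xc**2 / sxx
    press = float(((resid / (1.0 - h)) ** 2).sum())
    if tss == 0:
        return LoocvResult(q2=None, press=press, tss=0.0, n=n)
    return LoocvResult(q2=(1.0 - press / tss) * 100.0, press=press, tss=tss, n=n)


def q2_matrix(
    net: LayeredNetwork,
    predictor_layer: int = 1,
    drop_zeros: bool = False,
) -> RedundancyResult:
    """Q^2 of the predictor layer's degrees against every layer 1..max_ld.

    The diagonal (predictor vs itself) is an exact fit and scores 100.
    ``drop_zeros`` restricts each regression to clones with a nonzero degree
    in at least one of the two layers (sensitivity variant; the default
    keeps all clones, zero degrees included).  Layers whose degree vector is
    constant get an explicit ``None`` marker.
    """
    if net.max_ld < 2:
        raise ValueError("q2_matrix needs at least 2 computed layers")
    if not 1 <= predictor_layer <= net.max_ld:
        raise ValueError("predictor layer outside computed range")
    mat = layer_degree_matrix(net)
    if mat.shape[0] < 3:
        raise ValueError("LOOCV Q^2 requires at least 3 clones")
    x_full = mat[:, predictor_layer - 1].astype(float)
    result = RedundancyResult(sample_id=net.sample_id, predictor_layer=predictor_layer)
    for m in range(1, net.max_ld + 1):
        y_full = mat[:, m - 1].astype(float)
        if drop_zeros:
            keep = (x_full > 0) | (y_full > 0)
            x, y = x_full[keep], y_full[keep]
        else:
            x, y = x_full, y_full
        if x.size < 3 or np.ptp(y) == 0:
            result.per_layer[m] = (
                None if x.size < 3 else LoocvResult(None, 0.0, 0.0, int(x.size))
            )
            continue
        result.per_layer[m] = loocv_q2(x, y)
    return result
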