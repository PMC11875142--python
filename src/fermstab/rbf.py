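"""Radial-basis-function regression with confidence limits and
extrapolation (reliability) detection.

The predictive model is a single-hidden-layer Gaussian RBF network in
standardised input space,

    y_hat(x) = b + sum_h w_h * a_h(x),      a_h(x) = exp(-||x - c_h||^2 / (2 s_h^2)),

with centres ``c_h`` from seeded k-means on the training inputs, widths
``s_h`` proportional to each cluster's RMS radius, and output weights by
linear least squares.  Confidence limits are node-local: each hidden node
carries a half-width built from the activation-weighted residual sum of
squares around it, with a Student-t quantile at the node's effective
degrees of freedom, and a query's half-width is the activation-weighted
mix of the node half-widths.  Bands therefore widen where the fit is
locally poor.

Extrapolation detection uses a membership density.  For node ``h`` over
the ``K`` training inputs,

    rho_h = (1/K) * sum_k a_h(x_k),                                 (node density)

and for an arbitrary query ``x``,

    rho(x) = sum_h a_h(x) * rho_h / sum_h rho_h,                    (input density)

both bounded in [0, 1].  A second, *reliability* model regresses the
training-set densities on the inputs — implemented as a normalised RBF
(kernel-weighted mean) with one node per training point — and carries its
own node-local confidence limits.  A query is flagged unreliable
(extrapolating) when its actual input density falls outside the
reliability model's band: the query's membership of the basis is then not
predictable from the training data.  A least-squares reliability network
on the same basis cannot play this role, because the input density is an
exact linear function of the predictive activations and would be
reproduced with zero residual everywhere; the kernel-smoother form keeps
the comparison informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

__all__ = [
    "RBFNetwork",
    "ReliabilityModel",
    "PredictionWithBounds",
    "membership_density",
    "query_density",
    "fit_rbf",
    "activations",
    "node_density",
    "input_density",
    "rbf_confidence",
    "fit_reliability_model",
    "predict_with_reliability",
    "stability_surface",
]

#: Lower bound on kernel widths, in standardised input units.
WIDTH_FLOOR = 0.1
#: Scale applied to each cluster's RMS radius to obtain the node width.
WIDTH_SCALE = 0.75
#: Reliability-model kernels are this fraction of the parent node width.
RELIABILITY_WIDTH_SCALE = 0.5
#: Floor on the reliability band half-width, in density units.
RELIABILITY_BAND_FLOOR = 0.05


# ---------------------------------------------------------------------------
# density measures (pure functions of activation values)

def membership_density(activations_matrix) -> np.ndarray:
    """Node densities ``rho_h``: mean activation over the training set.

    ``activations_matrix`` has shape (K inputs, H nodes); each returned
    density lies in [0, 1], reaching 1 only if every training input sits
    at the node centre.
    """
    A = np.asarray(activations_matrix, dtype=float)
    if A.ndim != 2 or A.shape[0] == 0:
        raise ValueError("need a non-empty (K, H) activation matrix")
    return A.mean(axis=0)


def query_density(activation_vector, node_densities) -> float:
    """Input density ``rho(x)``: activation-weighted mean node density.

    With a single node this reduces to the node's activation itself.
    Raises when all node densities are zero (untrained/degenerate basis).
    """
    a = np.asarray(activation_vector, dtype=float)
    rho = np.asarray(node_densities, dtype=float)
    total = rho.sum()
    if total <= 0:
        raise ValueError("all node densities are zero; density undefined")
    return float(a @ rho / total)


# ---------------------------------------------------------------------------
# predictive network

@dataclass
class RBFNetwork:
    centers: np.ndarray          # (H, d) in standardised input space
    widths: np.ndarray           # (H,)
    output_weights: np.ndarray   # (H,)
    bias: float
    x_means: np.ndarray
    x_scales: np.ndarray
    y_mean: float
    y_scale: float
    node_densities: np.ndarray   # rho_h over the training inputs
    node_half_widths: np.ndarray  # per-node confidence half-width (std units)
    residual_scale: float        # sqrt(SSE / dof), standardized response
    dof: int
    alpha: float
    training_inputs_std: np.ndarray = field(repr=False)  # (K, d)
    training_node_index: np.ndarray = field(repr=False)  # cluster of each input

    @property
    def n_hidden(self) -> int:
        return len(self.centers)

    def _standardize(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.x_means):
            raise ValueError("query dimension does not match the network")
        return (X - self.x_means) / self.x_scales


def _gauss(Z, centers, widths):
    d2 = ((Z[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * widths[None, :] ** 2))


def fit_rbf(X, y, n_hidden=3, seed=0, *, alpha=0.05,
            width_scale=WIDTH_SCALE, width_floor=WIDTH_FLOOR,
            centers=None, widths=None, n_init=50) -> RBFNetwork:
    """Fit a Gaussian RBF network to (X, y).

    Inputs and response are standardised internally (sample sd, ddof=1).
    Centres come from seeded k-means on the standardised inputs unless
    given explicitly (``centers``/``widths`` in standardised space), and
    each node's width is ``width_scale`` times the RMS distance of its
    cluster's members from the centre, floored at ``width_floor``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    if n_hidden < 1:
        raise ValueError("need at least one hidden node")
    if centers is None and n <= n_hidden:
        raise ValueError("need more training points than hidden nodes")

    xm, xs = X.mean(axis=0), X.std(axis=0, ddof=1)
    xs = np.where(xs == 0, 1.0, xs)
    ym = y.mean()
    ysd = y.std(ddof=1)
    if ysd == 0:
        ysd = 1.0
    Z = (X - xm) / xs
    t = (y - ym) / ysd

    if centers is None:
        km = KMeans(n_clusters=n_hidden, n_init=n_init, random_state=seed,
                    algorithm="lloyd").fit(Z)
        C, labels = km.cluster_centers_, km.labels_
    else:
        C = np.asarray(centers, dtype=float)
        n_hidden = len(C)
        labels = np.argmin(((Z[:, None, :] - C[None, :, :]) ** 2).sum(2), axis=1)
    if widths is None:
        sig = np.empty(n_hidden)
        for h in range(n_hidden):
            members = Z[labels == h]
            if len(members) > 1:
                sig[h] = np.sqrt(((members - C[h]) ** 2).sum(axis=1).mean())
            else:
                sig[h] = width_floor
        sig = np.maximum(width_scale * sig, width_floor)
    else:
        sig = np.asarray(widths, dtype=float)
        if np.any(sig <= 0):
            raise ValueError("widths must be positive")
    if len(np.unique(C.round(12), axis=0)) < n_hidden:
        raise ValueError("coincident centres produce a degenerate basis")

    A = _gauss(Z, C, sig)
    Phi = np.column_stack([A, np.ones(n)])
    w, *_ = np.linalg.lstsq(Phi, t, rcond=None)
    resid = t - Phi @ w

    dof = n - n_hidden - 1
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    nh = A.sum(axis=0)                       # effective points per node
    sse_h = A.T @ resid ** 2                 # activation-weighted SSE
    nu_h = np.maximum(nh - 1.0, 2.0)         # node-local dof for the quantile
    tq = stats.t.ppf(1 - alpha / 2, nu_h)
    half = tq * np.sqrt(sse_h / np.maximum(nh - 1.0, 1.0))

    return RBFNetwork(
        centers=C, widths=sig,
        output_weights=w[:-1], bias=float(w[-1]),
        x_means=xm, x_scales=xs, y_mean=ym, y_scale=ysd,
        node_densities=membership_density(A),
        node_half_widths=half,
        residual_scale=float(np.sqrt(resid @ resid / dof)),
        dof=dof, alpha=alpha,
        training_inputs_std=Z,
        training_node_index=labels,
    )


def activations(net: RBFNetwork, X) -> np.ndarray:
    """Gaussian kernel values ``a_h(x)`` in (0, 1]; 1 at the node centre."""
    return _gauss(net._standardize(X), net.centers, net.widths)


def node_density(net: RBFNetwork, X_train=None) -> np.ndarray:
    """Node densities ``rho_h`` over training inputs (defaults to the fit's)."""
    if X_train is None:
        return net.node_densities
    return membership_density(activations(net, X_train))


def input_density(net: RBFNetwork, X) -> np.ndarray:
    """Input density ``rho(x)`` for one or more queries."""
    A = activations(net, X)
    return np.array([query_density(a, net.node_densities) for a in A])


def predict(net: RBFNetwork, X) -> np.ndarray:
    """Point predictions in response units."""
    A = activations(net, X)
    return net.y_mean + (A @ net.output_weights + net.bias) * net.y_scale


def rbf_confidence(net: RBFNetwork, X):
    """Predictions with node-local confidence limits.

    Returns ``(prediction, lower, upper)`` in response units.  The
    half-width at a query is the activation-weighted mix of the node
    half-widths, so regions dominated by a poorly fitting node get wider
    bands.
    """
    A = activations(net, X)
    pred = net.y_mean + (A @ net.output_weights + net.bias) * net.y_scale
    wsum = np.maximum(A.sum(axis=1), 1e-12)
    half = (A @ net.node_half_widths) / wsum * net.y_scale
    return pred, pred - half, pred + half


# ---------------------------------------------------------------------------
# reliability model

@dataclass
class ReliabilityModel:
    """Normalised-RBF regression of the training-set input density.

    One Gaussian kernel sits on every training input (width a fraction of
    its parent node's width); the model predicts the kernel-weighted mean
    of the training densities, with node-local confidence limits from the
    local dispersion of those densities.  Predicted densities are clipped
    to [0, 1] for reporting.
    """

    kernels: np.ndarray           # (K, d) standardised training inputs
    kernel_widths: np.ndarray     # (K,)
    training_densities: np.ndarray  # rho(x_k)
    kernel_half_widths: np.ndarray  # per-kernel band half-width (density units)
    x_means: np.ndarray
    x_scales: np.ndarray
    alpha: float

    def _eval(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        Z = (X - self.x_means) / self.x_scales
        A = _gauss(Z, self.kernels, self.kernel_widths)
        support = A.sum(axis=1)
        S = np.maximum(support, 1e-300)
        pred = (A @ self.training_densities) / S
        half = (A @ self.kernel_half_widths) / S
        return pred, half, support

    def predict(self, X):
        pred, _, _ = self._eval(X)
        return np.clip(pred, 0.0, 1.0)

    def confidence(self, X):
        """``(predicted density, lower, upper)``, clipped to [0, 1].

        Where a query activates no kernel at all (numerical underflow far
        outside the training support) the band is empty: lower > upper.
        """
        pred, half, support = self._eval(X)
        lo = np.clip(pred - half, 0.0, 1.0)
        hi = np.clip(pred + half, 0.0, 1.0)
        dead = support < 1e-12
        lo[dead], hi[dead] = 1.0, 0.0
        return np.clip(pred, 0.0, 1.0), lo, hi


def fit_reliability_model(net: RBFNetwork, X_train=None, *,
                          width_scale=RELIABILITY_WIDTH_SCALE,
                          band_floor=RELIABILITY_BAND_FLOOR) -> ReliabilityModel:
    """Build the reliability model adjacent to a fitted predictive network."""
    if X_train is None:
        Z = net.training_inputs_std
    else:
        Z = net._standardize(X_train)
    A = _gauss(Z, net.centers, net.widths)
    rho = np.array([query_density(a, net.node_densities) for a in A])

    labels = np.argmin(((Z[:, None, :] - net.centers[None, :, :]) ** 2).sum(2), axis=1)
    kw = np.maximum(width_scale * net.widths[labels], WIDTH_FLOOR)

    Ak = _gauss(Z, Z, kw)                    # kernel at every training point
    S = Ak.sum(axis=1)
    smoothed = (Ak @ rho) / S
    resid = rho - smoothed
    mass = Ak.sum(axis=0)
    local_sd = np.sqrt((Ak.T @ resid ** 2) / np.maximum(mass - 1.0, 1.0))
    tq = stats.t.ppf(1 - net.alpha / 2, net.dof)
    half = tq * np.maximum(local_sd, band_floor)

    return ReliabilityModel(
        kernels=Z, kernel_widths=kw,
        training_densities=rho,
        kernel_half_widths=half,
        x_means=net.x_means, x_scales=net.x_scales,
        alpha=net.alpha,
    )


@dataclass
class PredictionWithBounds:
    point: float
    lower: float
    upper: float
    density: float
    density_lower: float
    density_upper: float
    reliable: bool


def predict_with_reliability(net: RBFNetwork, rel: ReliabilityModel, X,
                             cap=None) -> list[PredictionWithBounds]:
    """Predict with confidence limits and an extrapolation flag.

    ``reliable`` is true when the query's actual input density (the
    activation-weighted node-density mix) lies inside the reliability
    model's confidence band at that query.  ``cap`` optionally bounds
    point predictions and limits from above (e.g. at the maximum
    observable stability duration of an experiment).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    pred, lo, hi = rbf_confidence(net, X)
    rho = input_density(net, X)
    dlo_pred, dlo, dhi = rel.confidence(X)
    if cap is not None:
        pred = np.minimum(pred, cap)
        lo = np.minimum(lo, cap)
        hi = np.minimum(hi, cap)
    out = []
    for i in range(len(X)):
        out.append(PredictionWithBounds(
            point=float(pred[i]), lower=float(lo[i]), upper=float(hi[i]),
            density=float(rho[i]),
            density_lower=float(dlo[i]), density_upper=float(dhi[i]),
            reliable=bool(dlo[i] <= rho[i] <= dhi[i]),
        ))
    return out


def stability_surface(net: RBFNetwork, rel: ReliabilityModel,
                      plasmid_sizes, conditions, cap=500.0):
    """Predicted stability across a plasmid-size grid per operating condition.

    ``conditions`` is an iterable of ``(dilution_rate, temperature)``
    pairs; the network must have been trained on inputs ordered
    (dilution rate, plasmid size, temperature).  Returns a list of dict
    rows with prediction, confidence limits, input density and the
    reliability flag; predictions are capped at ``cap`` hours when set.
    """
    plasmid_sizes = np.asarray(plasmid_sizes, dtype=float)
    rows = []
    for (D, T) in conditions:
        if plasmid_sizes.size == 0:
            continue
        Xg = np.column_stack([
            np.full(plasmid_sizes.shape, D),
            plasmid_sizes,
            np.full(plasmid_sizes.shape, T),
        ])
        for size, p in zip(plasmid_sizes, predict_with_reliability(net, rel, Xg, cap=cap)):
            rows.append({
                "dilution_rate": D, "temperature": T, "plasmid_size": float(size),
                "prediction": p.point, "lower": p.lower, "upper": p.upper,
                "density": p.density, "reliable": p.reliable,
            })
    return rows
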