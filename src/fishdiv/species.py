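"""Species-level occurrence model, LULC association, and TSS thresholding.

Presence/absence of a species across sites is modelled on the logit scale
with the same linear predictor as the richness model:

    logit(P_i) = a + b ln Q_i + [C(r) V]_i.

Because the observation is binary, this is fitted as a Bernoulli GLM with
logit link (penalized logistic regression), with the effective distance r
profiled over a grid exactly as in the richness model. A small ridge
penalty (default 1e-4) on (b, V) — never on the intercept — stabilizes
fits under quasi-complete separation, which is common with few sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decay import DEFAULT_KERNEL, SiteExposure

_MAX_ETA = 30.0


@dataclass
class SpeciesModelResult:
    species_id: str
    r: float
    a: float
    b: float
    V: np.ndarray
    loglik: float
    probabilities: np.ndarray
    converged: bool
    flag: str = ""
    tss_threshold: float | None = None
    tss: float | None = None
    profile_r: tuple[np.ndarray, np.ndarray] | None = None
    active_classes: list[int] = field(default_factory=list)

    @property
    def associated_class(self) -> int | None:
        if not self.converged:
            return None
        return assign_association(self)["class"]


def _ridge_logistic(X: np.ndarray, y: np.ndarray, ridge: float,
                    penalize: np.ndarray, max_iter: int = 100,
                    tol: float = 1e-10):
    """Penalized IRLS for logistic regression.

    ``penalize`` is a 0/1 vector over columns: 1 where the ridge applies.
    Returns (beta, penalized loglik, converged).
    """
    n, p = X.shape
    beta = np.zeros(p)
    D = np.diag(ridge * penalize)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -_MAX_ETA, _MAX_ETA)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        A = X.T @ (X * w[:, None]) + D
        b = X.T @ (w * z)
        try:
            beta_new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(A, b, rcond=None)[0]
        beta = beta_new
        eta = np.clip(X @ beta, -_MAX_ETA, _MAX_ETA)
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum()
                   - 0.5 * ridge * np.sum(penalize * beta**2))
        if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            converged = True
            break
        ll_old = ll
    return beta, ll, converged


def fit_species(presence, Q, fields=None, lulc=None, areas=None,
                exposure: SiteExposure | None = None,
                r_bounds: tuple[float, float] = (1.0, 500.0),
                n_grid: int = 25, ridge: float = 1e-4,
                kernel: str = DEFAULT_KERNEL,
                species_id: str = "species",
                min_per_class: int = 3) -> SpeciesModelResult:
    """Profile-r penalized logistic fit of one species' presence/absence.

    Species present at fewer than ``min_per_class`` sites (or absent at
    fewer) are flagged non-fittable and returned unconverged.
    """
    y = np.asarray(presence, float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("presence must be 0/1")
    if exposure is None:
        exposure = SiteExposure(fields, lulc, areas, kernel=kernel)
    n_pres = int(y.sum())
    n_abs = len(y) - n_pres
    K = exposure.n_classes
    if n_pres < min_per_class or n_abs < min_per_class:
        return SpeciesModelResult(
            species_id=species_id, r=float("nan"), a=float("nan"),
            b=float("nan"), V=np.full(K, np.nan), loglik=float("nan"),
            probabilities=np.full(len(y), np.nan), converged=False,
            flag=f"non-fittable: {n_pres} presences / {n_abs} absences")

    lnQ = np.log(np.asarray(Q, float))
    active = np.nonzero(exposure.counts.sum(axis=0) > 0)[0]
    penalize = np.array([0.0, 1.0] + [1.0] * len(active))

    r_grid = np.geomspace(r_bounds[0], r_bounds[1], n_grid)
    best = None
    lls = []
    for r in r_grid:
        C = exposure.matrix(r)[:, active]
        X = np.column_stack([np.ones(len(y)), lnQ, C])
        beta, ll, conv = _ridge_logistic(X, y, ridge, penalize)
        lls.append(ll)
        if best is None or ll > best[0]:
            best = (ll, r, beta, conv, X)
    ll, r_hat, beta, conv, X = best
    eta = np.clip(X @ beta, -_MAX_ETA, _MAX_ETA)
    prob = 1.0 / (1.0 + np.exp(-eta))
    flag = ""
    if np.max(np.abs(X @ beta)) > _MAX_ETA - 1:
        flag = "separation: linear predictor saturated (ridge-stabilized)"
    V = np.zeros(K)
    V[active] = beta[2:]
    return SpeciesModelResult(
        species_id=species_id, r=float(r_hat), a=float(beta[0]),
        b=float(beta[1]), V=V, loglik=float(ll), probabilities=prob,
        converged=bool(conv), flag=flag,
        profile_r=(r_grid, np.asarray(lls)),
        active_classes=[int(k) + 1 for k in active])


def fit_species_table(occ_df, Q, exposure: SiteExposure,
                      **kw) -> list[SpeciesModelResult]:
    """Fit every species column of an occurrence matrix (sites × species)."""
    results = []
    for col in occ_df.columns:
        if col == "site_id":
            continue
        results.append(fit_species(occ_df[col].to_numpy(), Q,
                                   exposure=exposure, species_id=col, **kw))
    return results


def assign_association(result: SpeciesModelResult) -> dict:
    """LULC class with the highest effect V_k; ties flagged, lowest index."""
    if not result.converged:
        raise ValueError("association undefined for unconverged fits")
    V = np.asarray(result.V, float)
    best = int(np.argmax(V)) + 1  # argmax takes the first (lowest) index
    tie = bool(np.sum(V == V.max()) > 1)
    return {"class": best, "tie": tie}


def tss_threshold(probabilities, labels) -> tuple[float, float]:
    """Presence threshold maximizing TSS = sensitivity + specificity − 1.

    Candidates are the unique predicted probabilities; prediction is
    ``p >= threshold``. Returns (lowest maximizing threshold, its TSS).
    """
    p = np.asarray(probabilities, float)
    y = np.asarray(labels, int)
    pos, neg = int((y == 1).sum()), int((y == 0).sum())
    if pos == 0 or neg == 0:
        raise ValueError("labels must contain both classes")
    best_thr, best_tss = None, -np.inf
    for thr in np.sort(np.unique(p)):
        pred = p >= thr
        sens = np.sum(pred & (y == 1)) / pos
        spec = np.sum(~pred & (y == 0)) / neg
        tss = sens + spec - 1.0
        if tss > best_tss + 1e-12:
            best_thr, best_tss = float(thr), float(tss)
    return best_thr, best_tss


def predict_species_map(result: SpeciesModelResult, channel_rcs,
                        lnQ_channel, C_channel,
                        threshold: float | None = None):
    """Binary presence per channel pixel from the species model.

    ``C_channel`` holds each channel pixel's decay-integrated exposures
    (local catchment within the species' r); returns (probabilities,
    presence) aligned with ``channel_rcs``.
    """
    if not result.converged:
        raise ValueError("cannot predict from an unconverged fit")
    thr = result.tss_threshold if threshold is None else threshold
    if thr is None:
        raise ValueError("no threshold available; run tss_threshold first")
    eta = result.a + result.b * np.asarray(lnQ_channel) \
        + np.asarray(C_channel) @ result.V
    prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -_MAX_ETA, _MAX_ETA)))
    return prob, prob >= thr
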