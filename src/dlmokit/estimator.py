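"""Scikit-learn style estimator wrapping the hockey-stick DLMO pipeline.

The breakpoint search is a curve fit: ``fit`` consumes one evening's
(time, concentration) samples and exposes the estimated onset and fitted
piecewise model; ``predict`` evaluates that model at new times. The
estimator composes with sklearn tooling (``get_params``/``set_params``,
``clone``) and keeps all tunables as constructor parameters.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import core
from .profile import DEFAULT_THRESHOLD, MelatoninProfile
from .segmentation import DEFAULT_LAMBDA, DEFAULT_MULTI_RISE_INTERVAL, DEFAULT_SEED
from .uncertainty import predict_piecewise


class HockeyStickDLMO(RegressorMixin, BaseEstimator):
    """Dim-light melatonin onset estimator (hockey-stick breakpoint fit).

    Parameters
    ----------
    threshold : float, default 2.3
        Ascending level in pg/mL separating baseline from rise.
    multi_rise_interval : float, default 2.0
        Hours; two rises closer than this resolve to the later one.
    coarse_t_step, coarse_y_step : float
        Coarse grid steps (0.1 h, 0.2 pg/mL).
    refine_t_step, refine_y_step : float
        Refinement grid steps (0.01 in both axes).
    slope_limit : float, default 0.2
        Early-fit slope clamp in pg/mL per hour.
    rule2_enabled, rule3_enabled : bool
        Toggles for the parallelogram and half-steepness truncation rules.
    lam : float, default 1e3
        Containment-penalty weight of the parallelogram objective.
    seed : int, default 1234
        Seed forwarded to stochastic parallelogram optimization routes.
    coarse_only : bool, default False
        Skip the refinement phase for a faster, approximate estimate.

    Attributes
    ----------
    dlmo_hours_ : float
        Estimated onset on the unwrapped decimal-hour axis.
    dlmo_clock_ : str
        The same, as "HH:MM" mod 24.
    dlmo_conc_ : float
        Concentration of the breakpoint, pg/mL.
    result_ : DlmoResult
        Full pipeline output (grids, labels, ROI, validation report).

    Examples
    --------
    >>> from dlmokit import HockeyStickDLMO, synthetic
    >>> truth = synthetic.generate_profile(onset=22.25, conc_cv=0.0)
    >>> est = HockeyStickDLMO().fit(truth.profile)
    >>> est.dlmo_clock_
    '22:15'
    """

    def __init__(
        self,
        threshold: float = DEFAULT_THRESHOLD,
        multi_rise_interval: float = DEFAULT_MULTI_RISE_INTERVAL,
        coarse_t_step: float = core.COARSE_T_STEP,
        coarse_y_step: float = core.COARSE_Y_STEP,
        refine_t_step: float = core.REFINE_STEP,
        refine_y_step: float = core.REFINE_STEP,
        slope_limit: float = core.SLOPE_LIMIT,
        rule2_enabled: bool = True,
        rule3_enabled: bool = True,
        lam: float = DEFAULT_LAMBDA,
        seed: int = DEFAULT_SEED,
        coarse_only: bool = False,
    ):
        self.threshold = threshold
        self.multi_rise_interval = multi_rise_interval
        self.coarse_t_step = coarse_t_step
        self.coarse_y_step = coarse_y_step
        self.refine_t_step = refine_t_step
        self.refine_y_step = refine_y_step
        self.slope_limit = slope_limit
        self.rule2_enabled = rule2_enabled
        self.rule3_enabled = rule3_enabled
        self.lam = lam
        self.seed = seed
        self.coarse_only = coarse_only

    @staticmethod
    def _as_profile(X, y=None) -> MelatoninProfile:
        if isinstance(X, MelatoninProfile):
            return X
        X = np.asarray(X, dtype=float)
        if y is not None:
            return MelatoninProfile(id="fit", times=X.ravel(), concentrations=np.asarray(y, float))
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError(
                "X must be a MelatoninProfile, an (n, 2) array of "
                "[time_hours, concentration], or times with y=concentrations"
            )
        return MelatoninProfile(id="fit", times=X[:, 0], concentrations=X[:, 1])

    def fit(self, X, y=None):
        """Estimate the DLMO from one profile.

        ``X`` may be a :class:`MelatoninProfile`, an (n, 2) array of
        [time, concentration], or a 1-D array of times with ``y`` the
        concentrations."""
        profile = self._as_profile(X, y)
        self.result_ = core.estimate_dlmo(
            profile,
            threshold=self.threshold,
            multi_rise_interval=self.multi_rise_interval,
            coarse_t_step=self.coarse_t_step,
            coarse_y_step=self.coarse_y_step,
            refine_t_step=self.refine_t_step,
            refine_y_step=self.refine_y_step,
            slope_limit=self.slope_limit,
            rule2_enabled=self.rule2_enabled,
            rule3_enabled=self.rule3_enabled,
            lam=self.lam,
            seed=self.seed,
            coarse_only=self.coarse_only,
        )
        self.dlmo_hours_ = self.result_.dlmo_hours
        self.dlmo_clock_ = self.result_.dlmo_clock
        self.dlmo_conc_ = self.result_.dlmo_conc
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        """Evaluate the fitted piecewise model at times ``X`` (hours)."""
        check_is_fitted(self, "result_")
        t = np.asarray(X, dtype=float).ravel()
        return predict_piecewise(self.result_, t)
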