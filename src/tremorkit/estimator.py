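"""scikit-learn style front end to the two-pass pipeline.

The two passes map naturally onto the estimator protocol: ``fit`` runs
Stage 1 (spectral peak candidates per recording) and Stage 2 (subject
frequency band) over a session, storing the learned band as
``frequency_bounds_``; ``predict`` runs the Stage-3 scan against that band
on the same or new recordings.  Parameters mirror
:class:`~tremorkit.params.AlgorithmParams` one-to-one, so the estimator
composes with sklearn's ``clone``/``get_params`` machinery and grid search.
"""

from __future__ import annotations

import pandas as pd
from sklearn.base import BaseEstimator

from .bounds import population_fallback
from .errors import NoTremorEvidenceError, RecordingTooShortError, StageOrderError
from .params import AlgorithmParams
from .quantify import SubjectReport, analyze_recording, quantify_analysis
from .records import ImuRecording


class TremorQuantifier(BaseEstimator):
    """Two-pass tremor quantifier over sessions of IMU recordings.

    Parameters are documented on :class:`~tremorkit.params.AlgorithmParams`.

    Attributes
    ----------
    frequency_bounds_ : FrequencyBounds
        Subject tremor band learned by ``fit`` (population fallback when the
        session shows no tremor evidence).
    n_peaks_ : int
        Number of candidate peaks pooled into the band estimate.
    """

    def __init__(
        self,
        window_s: float = 5.0,
        hop_s: float = 1.0,
        lag_fraction: float = 1.0,
        max_bin_hz: float = 0.0625,
        f_tremor_min: float = 1.5,
        f_lo_pop: float = 4.0,
        f_hi_pop: float = 12.0,
        max_peak_width: float = 3.0,
        p_min_pos_cm: float = 0.05,
        p_min_rot_deg: float = 0.05,
        p_min_ref_hz: float = 5.0,
        rho_min: float = 0.1,
        rho_d: float = 0.2,
        delta_f: float = 1.0,
        per_location_bounds: bool = False,
        f_action_min: float = 0.3,
        f_action_max: float = 3.0,
        action_threshold_cm: float = 2.0,
        f_pos_min: float = 0.25,
        action_window_s: float = 10.0,
        ahrs_tau_s: float = 2.0,
        ahrs_accel_gate: float = 0.3,
        trim_s: float = 1.0,
        exclude_undetected: bool = True,
    ):
        self.window_s = window_s
        self.hop_s = hop_s
        self.lag_fraction = lag_fraction
        self.max_bin_hz = max_bin_hz
        self.f_tremor_min = f_tremor_min
        self.f_lo_pop = f_lo_pop
        self.f_hi_pop = f_hi_pop
        self.max_peak_width = max_peak_width
        self.p_min_pos_cm = p_min_pos_cm
        self.p_min_rot_deg = p_min_rot_deg
        self.p_min_ref_hz = p_min_ref_hz
        self.rho_min = rho_min
        self.rho_d = rho_d
        self.delta_f = delta_f
        self.per_location_bounds = per_location_bounds
        self.f_action_min = f_action_min
        self.f_action_max = f_action_max
        self.action_threshold_cm = action_threshold_cm
        self.f_pos_min = f_pos_min
        self.action_window_s = action_window_s
        self.ahrs_tau_s = ahrs_tau_s
        self.ahrs_accel_gate = ahrs_accel_gate
        self.trim_s = trim_s
        self.exclude_undetected = exclude_undetected

    # ------------------------------------------------------------------

    def _params(self) -> AlgorithmParams:
        return AlgorithmParams(**{k: getattr(self, k) for k in self.get_params()})

    def fit(self, X: list[ImuRecording], y=None) -> "TremorQuantifier":
        """Learn the subject tremor band from a session of recordings."""
        from .bounds import estimate_frequency_bounds

        params = self._params()  # also validates
        if not isinstance(X, (list, tuple)) or not X:
            raise ValueError("X must be a non-empty list of ImuRecording")
        analyses = []
        for rec in X:
            try:
                analyses.append(analyze_recording(rec, params))
            except RecordingTooShortError:
                continue
        if not analyses:
            raise RecordingTooShortError("every recording is shorter than one analysis window")
        pooled = [pk for an in analyses for seg in an.peaks for pk in seg]
        nyquist = min(an.nyquist for an in analyses)
        try:
            self.frequency_bounds_ = estimate_frequency_bounds(pooled, params, nyquist=nyquist)
        except NoTremorEvidenceError:
            self.frequency_bounds_ = population_fallback(params)
        self.n_peaks_ = len(pooled)
        self._fit_analyses_ = analyses
        return self

    def predict(self, X: list[ImuRecording] | None = None) -> SubjectReport:
        """Stage-3 scan against the learned band.

        With ``X=None`` the recordings seen by ``fit`` are re-used (the
        standard second pass); otherwise new recordings are analysed
        against the same subject band.
        """
        if not hasattr(self, "frequency_bounds_"):
            raise StageOrderError("fit must run before predict")
        params = self._params()
        if X is None:
            analyses = self._fit_analyses_
        else:
            analyses = [analyze_recording(rec, params) for rec in X]
        reports = [quantify_analysis(an, self.frequency_bounds_, params) for an in analyses]
        return SubjectReport(
            bounds=self.frequency_bounds_, recordings=reports, params=params.to_dict()
        )

    def fit_predict(self, X: list[ImuRecording], y=None) -> SubjectReport:
        """The canonical two-pass run: fit the band, then re-scan the session."""
        return self.fit(X).predict()

    def transform(self, X: list[ImuRecording] | None = None) -> pd.DataFrame:
        """Per-segment results as a flat DataFrame (sklearn-pipeline friendly)."""
        return self.predict(X).to_frame()
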