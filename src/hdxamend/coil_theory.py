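"""Back/forward exchange controls predicted from random-coil theory.

After quench, a peptide's amides exchange at their intrinsic random-coil
rates along the fluidics timeline: transit through the pepsin column at
ambient temperature, then trapping and chromatography at the cold (quench)
temperature.  Back exchange is the piecewise-exponential decay of a fully
deuterated peptide into the protiated mobile phase; forward exchange is the
approach of a protonated peptide towards the small residual D2O fraction in
the quench (0.12% averaged over 3 min of trapping, by default).

The amides of the first two peptide positions are treated as exchanging
spontaneously (the position-1 amine is not an amide at all, and position 2
sits next to the free N-terminal ammonium, which catalyses exchange by
orders of magnitude), so they arrive fully equilibrated: zero deuterium in
back-exchange predictions, the ambient label fraction in forward-exchange
predictions.  Acetonitrile and column-interaction effects on the rates are
ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import (
    ControlTable,
    NoReporterError,
    Peptide,
    UptakeTable,
    get_logger,
)
from .exchange_artifacts import correct
from .intrinsic_rates import ExchangeConditions, compute_kint

logger = get_logger(__name__)

MIN_CONTROL_GAP = 1e-3


@dataclass(frozen=True)
class QuenchTimeline:
    """Post-quench fluidics timeline and conditions.

    Times are seconds; the per-peptide chromatographic retention time is
    supplied separately to the prediction functions.
    """

    trap_time: float = 180.0
    pepsin_transit: float = 0.0
    cold_temperature: float = 277.15
    ambient_temperature: float = 295.15
    ph_quench: float = 2.5
    d2o_fraction_trap: float = 0.0012
    apply_spontaneous: bool = True

    def __post_init__(self) -> None:
        if self.trap_time < 0 or self.pepsin_transit < 0:
            raise ValueError("times must be >= 0")
        if self.cold_temperature <= 0 or self.ambient_temperature <= 0:
            raise ValueError("temperatures must be positive Kelvin")
        if not 0.0 <= self.d2o_fraction_trap <= 1.0:
            raise ValueError("d2o_fraction_trap must be in [0, 1]")


def _segment_exponents(peptide: Peptide, timeline: QuenchTimeline,
                       retention_time: float, direction: str) -> tuple[np.ndarray, np.ndarray]:
    """Sum of k*t over timeline segments for each peptide residue.

    Returns (exponents, reporting_mask_over_peptide_positions).  Rates are
    evaluated on the peptide sequence (free termini included) at the quench
    pH, separately for the ambient and cold segments.
    """
    if len(peptide) < 3:
        raise NoReporterError(
            f"peptide {peptide.sequence!r} is too short to report back/forward exchange"
        )
    if retention_time < 0:
        raise ValueError("retention_time must be >= 0")
    exponent = np.zeros(len(peptide))
    reporting = None
    segments = (
        (timeline.pepsin_transit, timeline.ambient_temperature),
        (timeline.trap_time + retention_time, timeline.cold_temperature),
    )
    for duration, temperature in segments:
        if duration == 0:
            continue
        cond = ExchangeConditions(
            ph_read=timeline.ph_quench, temperature=temperature,
            direction=direction, pd_offset=0.0,
        )
        rates = compute_kint(peptide.sequence, cond)
        k = np.where(rates.mask, 0.0, np.nan_to_num(rates.k))
        exponent += k * duration
        reporting = ~rates.mask
    if reporting is None:  # zero-length timeline: still need the mask
        cond = ExchangeConditions(
            ph_read=timeline.ph_quench, temperature=timeline.cold_temperature,
            direction=direction, pd_offset=0.0,
        )
        reporting = ~compute_kint(peptide.sequence, cond).mask
    if not reporting.any():
        raise NoReporterError(f"peptide {peptide.sequence!r} has no reporting amides")
    return exponent, reporting


def predict_back_exchange(peptide: Peptide, timeline: QuenchTimeline,
                          retention_time: float) -> float:
    """Residual deuterium fraction (RFU_back) after the fluidics path.

    Starts from a fully deuterated peptide; each reporting amide decays as
    exp(-k_DH * t) piecewise over the timeline segments.
    """
    exponent, reporting = _segment_exponents(peptide, timeline, retention_time, "D_to_H")
    survival = np.exp(-exponent)
    if timeline.apply_spontaneous and reporting[1]:
        survival[1] = 0.0
    return float(survival[reporting].mean())


def predict_forward_exchange(peptide: Peptide, timeline: QuenchTimeline,
                             retention_time: float) -> float:
    """Artifactual deuterium uptake (RFU_fwd) from residual quench D2O.

    Starts protonated; each reporting amide approaches the trap label
    fraction as f_D * (1 - exp(-k_HD * t)) piecewise over the segments.
    """
    exponent, reporting = _segment_exponents(peptide, timeline, retention_time, "H_to_D")
    uptake = timeline.d2o_fraction_trap * (1.0 - np.exp(-exponent))
    if timeline.apply_spontaneous and reporting[1]:
        uptake[1] = timeline.d2o_fraction_trap
    return float(uptake[reporting].mean())


def coil_correct(
    table: UptakeTable,
    retention_times,
    timeline: QuenchTimeline | None = None,
    clip: bool = False,
) -> tuple[ControlTable, UptakeTable]:
    """Predict both controls for every peptide and reconstitute the table.

    Peptides whose predicted back control does not exceed the forward
    control are flagged, left uncorrected, and counted with a warning.
    """
    timeline = timeline or QuenchTimeline()
    retention_times = np.asarray(retention_times, dtype=float)
    if retention_times.shape != (table.map.n_peptides,):
        raise ValueError("one retention time required per peptide")
    back = np.empty(table.map.n_peptides)
    fwd = np.empty(table.map.n_peptides)
    for i, pep in enumerate(table.map.peptides):
        back[i] = predict_back_exchange(pep, timeline, retention_times[i])
        fwd[i] = predict_forward_exchange(pep, timeline, retention_times[i])

    flagged = back <= fwd
    if flagged.any():
        logger.warning("coil_correct: %d peptide(s) with predicted back <= fwd "
                       "left uncorrected", int(flagged.sum()))
    # keep the control table well-posed; flagged rows are not applied
    back_safe = np.where(flagged, np.minimum(fwd + MIN_CONTROL_GAP, 1.0), back)
    fwd_safe = np.where(flagged & (back_safe <= fwd), back_safe - MIN_CONTROL_GAP, fwd)
    controls = ControlTable(table.map, back_safe, np.clip(fwd_safe, 0, 1),
                            provenance="predicted_coil")
    controls.metadata = {"n_flagged": int(flagged.sum()),
                         "flagged_peptides": np.flatnonzero(flagged).tolist()}

    rfu = correct(table.rfu, back_safe[:, None], fwd_safe[:, None], clip=clip)
    rfu[flagged] = table.rfu[flagged]
    meta = dict(table.metadata)
    meta["coil_correct"] = {
        "trap_time": timeline.trap_time,
        "pepsin_transit": timeline.pepsin_transit,
        "n_flagged": int(flagged.sum()),
    }
    corrected = UptakeTable(table.map, table.times.copy(), rfu, meta)
    return controls, corrected
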