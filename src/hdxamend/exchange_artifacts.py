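"""Corruption/correction algebra for back and forward exchange artifacts.

Back exchange (label loss along the fluidics) and forward exchange (label
gain from residual D2O in the quench) together map the true uptake onto the
observed one through a per-peptide affine transform anchored at the two
experimental controls:

    corrupt:  RFU_err = RFU_true * (RFU_back - RFU_fwd) + RFU_fwd
    correct:  RFU_true = (RFU_err - RFU_fwd) / (RFU_back - RFU_fwd)

A fully exchanged sample (RFU_true = 1) reproduces the back control, an
unlabelled sample (RFU_true = 0) reproduces the forward control, and the two
maps are exact inverses whenever RFU_back > RFU_fwd.
"""

from __future__ import annotations

import numpy as np

from .core_io import (
    AlignmentError,
    ControlTable,
    DegenerateControlsError,
    UptakeTable,
    get_logger,
)

logger = get_logger(__name__)


def _check_controls(back, fwd) -> None:
    back = np.asarray(back, dtype=float)
    fwd = np.asarray(fwd, dtype=float)
    if np.any(back <= fwd):
        raise DegenerateControlsError("rfu_back must be strictly greater than rfu_fwd")


def corrupt(rfu_true, back, fwd):
    """Observed (erroneous) RFU produced by back/forward exchange.

    Affine and strictly increasing in ``rfu_true``; compresses the dynamic
    range [0, 1] onto [fwd, back].
    """
    _check_controls(back, fwd)
    rfu_true = np.asarray(rfu_true, dtype=float)
    out = rfu_true * (np.asarray(back) - np.asarray(fwd)) + np.asarray(fwd)
    return float(out) if out.ndim == 0 else out


def correct(rfu_err, back, fwd, clip: bool = False):
    """Reconstitute the true RFU from observed data and the two controls.

    Exact inverse of :func:`corrupt` when ``clip`` is False.  With ``clip``
    the result is clamped to [0, 1]; out-of-range cells diagnose inaccurate
    controls and are counted in the log.
    """
    _check_controls(back, fwd)
    rfu_err = np.asarray(rfu_err, dtype=float)
    out = (rfu_err - np.asarray(fwd)) / (np.asarray(back) - np.asarray(fwd))
    if clip:
        n_out = int(np.sum((out < 0) | (out > 1)))
        if n_out:
            logger.warning("correct: clipped %d cells outside [0, 1]", n_out)
        out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def apply_controls(
    table: UptakeTable, controls: ControlTable, mode: str, clip: bool = False
) -> UptakeTable:
    """Apply :func:`corrupt` or :func:`correct` element-wise over a table."""
    if mode not in ("corrupt", "correct"):
        raise ValueError(f"mode must be 'corrupt' or 'correct', got {mode!r}")
    if table.map.peptides != controls.map.peptides:
        ours = {(p.sequence, p.start, p.end) for p in table.map.peptides}
        theirs = {(p.sequence, p.start, p.end) for p in controls.map.peptides}
        missing = ours - theirs
        if missing:
            seq, start, end = sorted(missing)[0]
            raise AlignmentError(
                f"no control pair for peptide {seq!r} ({start}-{end})"
            )
        raise AlignmentError("control table peptides do not align with the uptake table")
    back = controls.rfu_back[:, None]
    fwd = controls.rfu_fwd[:, None]
    if mode == "corrupt":
        rfu = corrupt(table.rfu, back, fwd)
    else:
        rfu = correct(table.rfu, back, fwd, clip=clip)
    meta = dict(table.metadata)
    meta["exchange_artifacts"] = {
        "mode": mode, "clip": clip, "controls_provenance": controls.provenance,
    }
    return UptakeTable(table.map, table.times.copy(), rfu, meta)
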