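"""Pulse-amplitude-modulated fluorescence processing: NPQ per pulse, Fv/Fm,
quality filtering and technical-replicate averaging.

NPQ at each saturating pulse uses the Stern-Volmer definition
``NPQ = (Fm - Fm') / Fm' = Fm/Fm' - 1`` with Fm from overnight dark
adaptation, and ``Fv/Fm = (Fm - F0)/Fm`` from the dark-adapted F0 and Fm
measured before the actinic sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocol import PHASES

__all__ = [
    "FluorescenceTrace",
    "NPQSeries",
    "compute_npq",
    "qc_filter",
    "average_replicates",
    "read_trace_csv",
    "write_trace_csv",
    "PARAM_COLUMNS",
]

#: the six kinetic quantities carried through the pipeline
PARAM_COLUMNS = ("a_qe", "tau_qe", "a_qm", "tau_qm", "a_qi", "max_npq")

FVFM_THRESHOLD = 0.75


@dataclass
class FluorescenceTrace:
    """One leaf disk's dark-adapted Fm/F0 and timed Fm' pulse series.

    ``pulses`` is a DataFrame with columns phase, t_min, fm_prime (t_min is
    minutes within the phase).
    """

    disk_id: str
    plot_id: str
    genotype: str
    date: str
    fm_dark: float
    f0_dark: float
    pulses: pd.DataFrame

    def __post_init__(self):
        if not (self.fm_dark > self.f0_dark > 0):
            raise ValueError("require fm_dark > f0_dark > 0")
        if (self.pulses["fm_prime"] <= 0).any():
            raise ValueError("all fm_prime values must be > 0")


@dataclass
class NPQSeries:
    """Per-pulse NPQ values for one disk plus its dark-adapted Fv/Fm."""

    disk_id: str
    plot_id: str
    genotype: str
    date: str
    fv_fm: float
    data: pd.DataFrame  # columns: phase, t_min, npq
    qc_pass: bool = True
    qc_reason: str = ""

    def phase(self, name: str) -> pd.DataFrame:
        if name not in PHASES:
            raise ValueError(f"unknown phase {name!r}")
        return self.data[self.data["phase"] == name]


def compute_npq(trace: FluorescenceTrace) -> NPQSeries:
    """NPQ = Fm/Fm' - 1 at every pulse; Fv/Fm from the dark-adapted values."""
    npq = trace.fm_dark / trace.pulses["fm_prime"].to_numpy(dtype=float) - 1.0
    fv_fm = (trace.fm_dark - trace.f0_dark) / trace.fm_dark
    data = pd.DataFrame(
        {
            "phase": trace.pulses["phase"].to_numpy(),
            "t_min": trace.pulses["t_min"].to_numpy(dtype=float),
            "npq": npq,
        }
    )
    return NPQSeries(
        disk_id=trace.disk_id,
        plot_id=trace.plot_id,
        genotype=trace.genotype,
        date=trace.date,
        fv_fm=fv_fm,
        data=data,
    )


def qc_filter(fits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the disk-level quality filters.

    ``fits`` is a disk-level table with a ``fv_fm`` column and the six
    parameter columns.  Disks are excluded when Fv/Fm < 0.75 (unhealthy
    tissue) or when any fitted parameter is negative.  Returns the surviving
    rows and an exclusion log with one row per removed disk and the reason.
    The filter is idempotent and exclusions + survivors partition the input.
    """
    fits = fits.reset_index(drop=True)
    param_cols = [c for c in PARAM_COLUMNS if c in fits.columns]
    reasons = []
    for _, row in fits.iterrows():
        if row["fv_fm"] < FVFM_THRESHOLD:
            reasons.append("fv_fm<0.75")
        elif any(row[c] < 0 for c in param_cols):
            reasons.append("negative parameter")
        elif "converged" in fits.columns and not row["converged"]:
            reasons.append("fit not converged")
        else:
            reasons.append("")
    reasons = pd.Series(reasons, index=fits.index)
    excluded = reasons != ""
    log = fits.loc[excluded, ["disk_id", "plot_id", "genotype", "date"]].copy()
    log["reason"] = reasons[excluded].to_numpy()
    kept = fits.loc[~excluded].reset_index(drop=True)
    if kept.empty:
        warnings.warn("qc_filter removed every disk", stacklevel=2)
    return kept, log.reset_index(drop=True)


def average_replicates(
    fits: pd.DataFrame, by: tuple[str, ...] = ("genotype", "plot_id", "date")
) -> pd.DataFrame:
    """Average technical replicates (leaf disks) to plot level.

    Returns one row per ``by`` group with the arithmetic mean of each kinetic
    parameter and ``n_disks`` recording how many disks contributed.  Groups
    with zero surviving disks simply do not appear (dropped, not imputed).
    """
    if fits.empty:
        warnings.warn("no disks to average", stacklevel=2)
        return pd.DataFrame(columns=[*by, *PARAM_COLUMNS, "n_disks"])
    param_cols = [c for c in PARAM_COLUMNS if c in fits.columns]
    grouped = fits.groupby(list(by), sort=True, observed=True)
    out = grouped[param_cols].mean()
    out["n_disks"] = grouped.size()
    return out.reset_index()


# ---------------------------------------------------------------------------
# CSV I/O

_LONG_COLUMNS = [
    "disk_id",
    "plot_id",
    "genotype",
    "date",
    "fm_dark",
    "f0_dark",
    "phase",
    "t_min",
    "fm_prime",
]


def write_trace_csv(traces, path) -> None:
    """Write traces in the long pulse-table dialect (one row per pulse)."""
    rows = []
    for tr in traces:
        for _, p in tr.pulses.iterrows():
            rows.append(
                (tr.disk_id, tr.plot_id, tr.genotype, tr.date, tr.fm_dark, tr.f0_dark, p["phase"], p["t_min"], p["fm_prime"])
            )
    pd.DataFrame(rows, columns=_LONG_COLUMNS).to_csv(path, index=False)


def read_trace_csv(path) -> list[FluorescenceTrace]:
    """Read a pulse table CSV (long format, or wide one-row-per-disk).

    Wide format is detected by the absence of a ``phase`` column; pulse
    columns are then named ``<phase>_<t_min>`` (e.g. ``lowlight2_2.5``).
    """
    df = pd.read_csv(path)
    if "phase" not in df.columns:
        df = _wide_to_long(df)
    traces = []
    for disk_id, grp in df.groupby("disk_id", sort=True):
        first = grp.iloc[0]
        pulses = grp[["phase", "t_min", "fm_prime"]].reset_index(drop=True)
        traces.append(
            FluorescenceTrace(
                disk_id=str(disk_id),
                plot_id=str(first["plot_id"]),
                genotype=str(first["genotype"]),
                date=str(first["date"]),
                fm_dark=float(first["fm_dark"]),
                f0_dark=float(first["f0_dark"]),
                pulses=pulses,
            )
        )
    return traces


def _wide_to_long(df: pd.DataFrame) -> pd.DataFrame:
    id_cols = ["disk_id", "plot_id", "genotype", "date", "fm_dark", "f0_dark"]
    pulse_cols = [c for c in df.columns if c not in id_cols]
    records = []
    for _, row in df.iterrows():
        for col in pulse_cols:
            phase, t = col.rsplit("_", 1)
            if phase not in PHASES:
                raise ValueError(f"unrecognized pulse column {col!r}")
            records.append({**{k: row[k] for k in id_cols}, "phase": phase, "t_min": float(t), "fm_prime": row[col]})
    return pd.DataFrame(records)
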