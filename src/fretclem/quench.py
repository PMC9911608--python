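"""Membrane-plane FRET quenching by dipicrylamine (DPA).

DPA is a nonfluorescent hydrophobic anion that partitions into the plasma
membrane and quenches nearby fluorophores by FRET.  Because the membrane
plane is fixed, the quenching efficiency reports the axial distance of a
fluorophore above the membrane: constructs whose fluorophore sits close to
the membrane lose more lifetime on DPA addition than constructs whose
fluorophore sits higher in the cytoplasm.

The transfer model integrates pairwise Förster rates from a point donor at
height z over an infinite plane of acceptors at surface density sigma:

    S(z) = pi * sigma * R0^6 / (2 z^4),      E = S / (1 + S)

(the point-to-plane integral of (R0/r)^-6 over the plane).  Only the
ordering of constructs by lifetime change is contractual — sigma maps to
DPA concentration through an uncharacterised proportionality, so no
absolute axial distance is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, MissingPairError

__all__ = [
    "QuenchPlane",
    "plane_quench_efficiency",
    "sigma_for_half_quench",
    "delta_lifetime_axial_rank",
]


@dataclass(frozen=True)
class QuenchPlane:
    """Point donor above an infinite acceptor plane.

    sigma: acceptor surface density (per Å², proportional to DPA
    concentration); R0_dpa: Förster radius of the fluorophore–DPA pair (Å);
    z: axial donor height above the plane (Å).
    """

    sigma: float
    R0_dpa: float
    z: float

    def __post_init__(self):
        if self.sigma < 0:
            raise InvalidParameterError("sigma must be >= 0")
        if self.R0_dpa <= 0:
            raise InvalidParameterError("R0_dpa must be positive")
        if self.z <= 0:
            raise InvalidParameterError("z must be positive")


def plane_quench_efficiency(plane: QuenchPlane) -> float:
    """Quenching efficiency of a fluorophore at height z above the DPA plane.

    E = S / (1 + S), S = pi * sigma * R0^6 / (2 z^4); strictly decreasing
    in z and increasing in sigma.  E = 0.5 at
    z* = (pi sigma R0^6 / 2)^(1/4).
    """
    S = math.pi * plane.sigma * plane.R0_dpa**6 / (2.0 * plane.z**4)
    return S / (1.0 + S)


def sigma_for_half_quench(z: float, R0_dpa: float) -> float:
    """Acceptor density giving 50% quenching at height z (inverts S = 1)."""
    if z <= 0 or R0_dpa <= 0:
        raise InvalidParameterError("z and R0_dpa must be positive")
    return 2.0 * z**4 / (math.pi * R0_dpa**6)


def delta_lifetime_axial_rank(records: pd.DataFrame) -> pd.DataFrame:
    """Rank constructs by lifetime loss on quencher addition.

    ``records`` has columns ``construct``, ``condition`` in
    {"control", "dpa"} and ``tau_mean_ns`` (replicates allowed; they are
    averaged per construct and condition).  Returns a DataFrame sorted by
    delta_tau_ns = tau(control) - tau(dpa) descending: larger lifetime loss
    means closer to the membrane.  Ties keep input order.  Only the ranking
    is meaningful; no absolute distance is derived.

    Raises
    ------
    MissingPairError
        A construct lacks either its control or its dpa measurement.
    """
    need = {"construct", "condition", "tau_mean_ns"}
    if need - set(records.columns):
        raise InvalidParameterError(f"records needs columns {sorted(need)}")
    bad = set(records["condition"]) - {"control", "dpa"}
    if bad:
        raise InvalidParameterError(f"unknown conditions: {sorted(bad)}")
    order = {c: i for i, c in enumerate(pd.unique(records["construct"]))}
    means = (
        records.groupby(["construct", "condition"], sort=False)["tau_mean_ns"]
        .mean()
        .unstack("condition")
    )
    missing = means.index[means.isna().any(axis=1)].tolist()
    if missing or means.shape[1] < 2:
        missing = missing or means.index.tolist()
        raise MissingPairError(
            f"constructs missing a paired condition: {missing}"
        )
    out = pd.DataFrame(
        {
            "construct": means.index,
            "tau_control_ns": means["control"].to_numpy(),
            "tau_dpa_ns": means["dpa"].to_numpy(),
        }
    )
    out["delta_tau_ns"] = out["tau_control_ns"] - out["tau_dpa_ns"]
    out["_in"] = out["construct"].map(order)
    out = (
        out.sort_values(["delta_tau_ns", "_in"], ascending=[False, True])
        .drop(columns="_in")
        .reset_index(drop=True)
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out
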