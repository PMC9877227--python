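"""Bookkeeping constants for the full-scale MLKL plasma-membrane study setup.

These describe the reference simulation campaign the analyses were designed
around: four replicas of a single MLKL monomer over a 1200-lipid bilayer
(600 per leaflet) of DOPC:Chol:DOPE:PIP:PIP2 at 40:32:20:4:4 mol%, run from
different initial protein orientations. They are inputs for manifest
arithmetic (e.g. total simulated time) and for full-scale synthetic configs,
not fitted quantities.
"""

from __future__ import annotations

__all__ = [
    "REPLICA_TIMES_NS",
    "REPLICA_BOXES_NM",
    "LIPIDS_PER_LEAFLET",
    "COMPOSITION_MOLFRAC",
    "DEEPEST_RESIDUE",
    "total_simulated_time_us",
]

#: Production length of each replica, ns.
REPLICA_TIMES_NS = {"Rep1": 2180, "Rep2": 2180, "Rep3": 2200, "Rep4": 2200}

#: Orthorhombic box vectors (x, y, z) in nm for each replica.
REPLICA_BOXES_NM = {
    "Rep1": (17.1, 17.1, 22.3),
    "Rep2": (17.2, 17.2, 21.9),
    "Rep3": (17.3, 17.3, 18.4),
    "Rep4": (17.3, 17.3, 18.2),
}

LIPIDS_PER_LEAFLET = 600

COMPOSITION_MOLFRAC = {"DOPC": 0.40, "CHOL": 0.32, "DOPE": 0.20,
                       "PIP": 0.04, "PIP2": 0.04}

#: Deepest inserted protein residue per replica (Cα reference for RDFs).
DEEPEST_RESIDUE = {"Rep1": 268, "Rep2": 53, "Rep3": 53, "Rep4": 406}


def total_simulated_time_us() -> float:
    """Sum of the per-replica production times, in microseconds."""
    return sum(REPLICA_TIMES_NS.values()) / 1000.0
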