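"""Canonical resting-state network labels.

The eight Yeo/Schaefer networks used throughout the package. The order is
fixed and global: it defines spider-plot ordering and breaks argmax ties
(earlier label wins).
"""

from __future__ import annotations

NETWORKS: tuple[str, ...] = (
    "Vis",
    "SomMot",
    "DAN",
    "VAN",
    "Limbic",
    "FPN",
    "TempPar",
    "DMN",
)

N_NETWORKS = len(NETWORKS)

_INDEX = {name: i for i, name in enumerate(NETWORKS)}


def network_index(name: str) -> int:
    """Position of a network label in the fixed canonical order."""
    try:
        return _INDEX[name]
    except KeyError:
        raise ValueError(
            f"unknown network {name!r}; expected one of {NETWORKS}"
        ) from None


def validate_network(name: str) -> str:
    network_index(name)
    return name
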