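"""Published dissociation constants for STAM2 UIM-SH3 linker variants.

These literature values (µM, mean ± SD over residues) for the wild-type
UIM-SH3 dual domain (US-WT) and its linker-shortened or domain-deleted
variants binding monoubiquitin and Lys63-linked diubiquitin serve as
ground truths for simulation-based recovery studies and for derived
quantities such as the avidity loss on linker shortening.  ``model``
records which isotherm was used: Ub titrations and the single-domain
constructs follow the 1:1 model; the bivalent Lys63-Ub₂ binding of the
two-domain constructs follows the 2:1 model.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class KdEntry:
    construct: str
    domain: str  # binding-site domain; "" for single-domain constructs
    ligand: str  # "Ub" or "Ub2"
    Kd: float  # µM
    sd: float  # µM
    model: str  # isotherm used: "1to1" or "2to1"


KD_TABLE: tuple[KdEntry, ...] = (
    KdEntry("US-WT", "UIM", "Ub", 86.0, 31.0, "1to1"),
    KdEntry("US-WT", "UIM", "Ub2", 78.0, 59.0, "2to1"),
    KdEntry("US-WT", "SH3", "Ub", 267.0, 119.0, "1to1"),
    KdEntry("US-WT", "SH3", "Ub2", 60.0, 28.0, "2to1"),
    KdEntry("US-D1", "UIM", "Ub", 148.0, 60.0, "1to1"),
    KdEntry("US-D1", "UIM", "Ub2", 137.0, 57.0, "2to1"),
    KdEntry("US-D1", "SH3", "Ub", 394.0, 127.0, "1to1"),
    KdEntry("US-D1", "SH3", "Ub2", 253.0, 163.0, "2to1"),
    KdEntry("US-D2", "UIM", "Ub", 203.0, 91.0, "1to1"),
    KdEntry("US-D2", "UIM", "Ub2", 99.0, 50.0, "2to1"),
    KdEntry("US-D2", "SH3", "Ub", 669.0, 234.0, "1to1"),
    KdEntry("US-D2", "SH3", "Ub2", 483.0, 196.0, "2to1"),
    KdEntry("US-D3", "", "Ub", 266.0, 96.0, "1to1"),
    KdEntry("US-D3", "", "Ub2", 39.0, 22.0, "1to1"),
    KdEntry("US-D4", "", "Ub", 158.0, 79.0, "1to1"),
    KdEntry("US-D4", "", "Ub2", 97.0, 49.0, "1to1"),
)


def lookup_kd(construct: str, ligand: str, domain: str = "") -> KdEntry:
    for e in KD_TABLE:
        if e.construct == construct and e.ligand == ligand and e.domain == domain:
            return e
    raise KeyError(f"no entry for {construct}/{domain or '-'}/{ligand}")


def avidity_ratio(ligand: str = "Ub2", domain: str = "SH3",
                  weak: str = "US-D2", tight: str = "US-WT") -> float:
    """Fold-loss in affinity between two constructs for the same site and
    ligand, Kd(weak)/Kd(tight) — e.g. the factor by which SH3 binding of
    Lys63-Ub₂ weakens when the linker is shortened by 14 residues."""
    return lookup_kd(weak, ligand, domain).Kd / lookup_kd(tight, ligand, domain).Kd


#: reference mean R2 of the isolated UIM helix (s⁻¹) at its ~4.0 kDa mass,
#: used as one calibrant of the R2-vs-mass molecular ruler
UIM_CALIBRANT = (4.0, 5.1)
UIM_CALIBRANT_SD = 0.6
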