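"""Per-residue contact bookkeeping between two structures of one protein.

Used to ask which residues gain and which lose intra-chain contacts when a
receptor binds its ligand: contacts are counted per residue in the free
and in the bound structure (distance-cutoff criterion), residues are
matched by author numbering, and the per-residue difference is classified
as gained / lost / unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .gomodel import CGStructure, build_contact_map

__all__ = [
    "ContactChangeProfile",
    "residue_contact_counts",
    "net_contact_change",
    "write_profile",
]


@dataclass
class ContactChangeProfile:
    """Net per-residue contact change (bound − free) over matched residues."""

    residue_ids: list[int]
    count_free: list[int]
    count_bound: list[int]
    net_change: list[int]
    classification: list[Literal["gained", "lost", "unchanged"]]
    unmatched_free: list[int]
    unmatched_bound: list[int]

    def as_rows(self):
        return zip(
            self.residue_ids,
            self.count_free,
            self.count_bound,
            self.net_change,
            self.classification,
        )


def residue_contact_counts(
    structure: CGStructure,
    method: Literal["heavy_atom", "calpha"] = "heavy_atom",
    cutoff_A: float | None = None,
) -> dict[int, int]:
    """Contact-partner count per residue, keyed by author residue number.

    A contact (i, j) increments both partners; the criterion is the same
    distance proxy used for the Go-model contact map.
    """
    cmap = build_contact_map(structure, method=method, cutoff_A=cutoff_A)
    counts = cmap.partner_counts(structure.n_residues)
    return {num: int(c) for num, c in zip(structure.residue_numbers, counts)}


def net_contact_change(
    free_counts: dict[int, int],
    bound_counts: dict[int, int],
) -> ContactChangeProfile:
    """Per-residue bound − free contact difference over matched residues.

    Residues present in only one structure are reported and excluded.
    Antisymmetric under argument swap; identical inputs give an all-zero,
    all-"unchanged" profile.
    """
    matched = sorted(set(free_counts) & set(bound_counts))
    if not matched:
        raise ValueError("no residues match between the two structures")
    unmatched_free = sorted(set(free_counts) - set(bound_counts))
    unmatched_bound = sorted(set(bound_counts) - set(free_counts))
    cf = [free_counts[r] for r in matched]
    cb = [bound_counts[r] for r in matched]
    net = [b - f for f, b in zip(cf, cb)]
    cls = ["gained" if n > 0 else "lost" if n < 0 else "unchanged" for n in net]
    return ContactChangeProfile(
        residue_ids=matched,
        count_free=cf,
        count_bound=cb,
        net_change=net,
        classification=cls,  # type: ignore[arg-type]
        unmatched_free=unmatched_free,
        unmatched_bound=unmatched_bound,
    )


def write_profile(profile: ContactChangeProfile, path: str | Path) -> None:
    """Write the profile as tab-separated text."""
    with Path(path).open("w") as fh:
        if profile.unmatched_free:
            fh.write(f"#unmatched_free={','.join(map(str, profile.unmatched_free))}\n")
        if profile.unmatched_bound:
            fh.write(f"#unmatched_bound={','.join(map(str, profile.unmatched_bound))}\n")
        fh.write("residue_id\tcount_free\tcount_bound\tnet_change\tclass\n")
        for rid, f, b, n, c in profile.as_rows():
            fh.write(f"{rid}\t{f}\t{b}\t{n}\t{c}\n")
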