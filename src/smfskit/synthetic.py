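"""Synthetic data generators standing in for the AFM instrument and for
crystal structures.

``generate_trace`` builds multi-event worm-like-chain sawtooth curves with
a known two-population joint (ΔLc, rupture force) truth, thermal force
noise, a tip-adhesion first peak and a detachment last peak — the parts of
a real pulling cycle the downstream analysis must cope with.  What it does
not emulate: instrument drift, multiple tethers, cantilever ringing.

``generate_toy_structure`` builds multi-domain Cα-only β-meander proteins
with defined native contacts and domain boundaries for simulator tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .gomodel import CGStructure
from .polymer import PhysicalConstants, WLCParams, wlc_force, wlc_inverse_extension
from .traces import ForceExtensionTrace

__all__ = [
    "EventFamily",
    "TraceGenConfig",
    "ToyStructureConfig",
    "TraceTruth",
    "reference_truth_families",
    "generate_trace",
    "generate_ensemble",
    "generate_toy_structure",
    "write_truth_fixture",
    "read_truth_fixture",
]


@dataclass(frozen=True)
class EventFamily:
    """One unfolding-event population: joint normal (ΔLc, F) marginals."""

    dlc_mean_nm: float
    dlc_sd_nm: float
    force_mean_pN: float
    force_sd_pN: float
    weight: float

    def __post_init__(self) -> None:
        if self.dlc_sd_nm <= 0 or self.force_sd_pN <= 0:
            raise ValueError("standard deviations must be > 0")
        if not (0 <= self.weight <= 1):
            raise ValueError("weight must lie in [0, 1]")


def reference_truth_families() -> list[EventFamily]:
    """The repository's two-population ground truth.

    Centers follow the measured populations (ΔLc 16 and 36 nm; rupture
    forces 90 and 40 pN, the short features requiring the higher forces);
    the spreads (4/8 nm, 25/12 pN) and equal weights are fixture choices.
    """
    return [
        EventFamily(dlc_mean_nm=16.0, dlc_sd_nm=4.0,
                    force_mean_pN=90.0, force_sd_pN=25.0, weight=0.5),
        EventFamily(dlc_mean_nm=36.0, dlc_sd_nm=8.0,
                    force_mean_pN=40.0, force_sd_pN=12.0, weight=0.5),
    ]


@dataclass(frozen=True)
class TraceGenConfig:
    """Settings of the sawtooth generator."""

    families: tuple[EventFamily, ...] = tuple(reference_truth_families())
    n_events_range: tuple[int, int] = (2, 4)
    initial_Lc_nm: float = 30.0
    noise_sd_pN: float = 6.0
    sample_step_nm: float = 0.5
    adhesion_peak: bool = True
    detachment: bool = True
    p_nm: float = 0.36
    pulling_speed_nm_s: float = 200.0
    cantilever_k_N_m: float = 0.025

    def __post_init__(self) -> None:
        lo, hi = self.n_events_range
        if not (1 <= lo <= hi <= 10):
            raise ValueError("events per trace must lie within (1, 10)")
        if abs(sum(f.weight for f in self.families) - 1.0) > 1e-9:
            raise ValueError("family weights must sum to 1")
        for name in ("initial_Lc_nm", "sample_step_nm", "p_nm",
                     "pulling_speed_nm_s", "cantilever_k_N_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd_pN < 0:
            raise ValueError("noise_sd_pN must be >= 0")


@dataclass
class TraceTruth:
    """Ground truth of one generated trace."""

    trace_id: str
    seed: int
    events: list[tuple[float, float]]  # (ΔLc_nm, rupture force pN), drawn jointly
    family_index: list[int]
    total_Lc_nm: float


def _draw_event(
    rng: np.random.Generator, families: Sequence[EventFamily], weights: np.ndarray
) -> tuple[int, float, float]:
    """Draw (family, ΔLc, F); redraw non-positive values up to 100 times."""
    k = int(rng.choice(len(families), p=weights))
    fam = families[k]
    for _ in range(100):
        dlc = rng.normal(fam.dlc_mean_nm, fam.dlc_sd_nm)
        force = rng.normal(fam.force_mean_pN, fam.force_sd_pN)
        if dlc > 0 and force > 0:
            return k, float(dlc), float(force)
    raise RuntimeError("could not draw a positive (ΔLc, F) pair in 100 attempts")


def generate_trace(
    config: TraceGenConfig,
    seed: int,
    trace_id: str | None = None,
    consts: PhysicalConstants = PhysicalConstants(),
) -> tuple[ForceExtensionTrace, TraceTruth]:
    """One synthetic sawtooth pulling cycle with recorded ground truth.

    The cycle is a sequence of WLC branches with cumulative contour lengths
    Lc_1 = initial_Lc, Lc_{i+1} = Lc_i + ΔLc_i; branch i ends by rupture at
    its drawn force F_i, at the extension where the WLC reaches that force.
    An optional adhesion spike sits near zero extension and the final
    branch ends in a detachment drop to the baseline; Gaussian force noise
    is added throughout.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    weights = np.array([f.weight for f in config.families])
    n_events = int(rng.integers(config.n_events_range[0], config.n_events_range[1] + 1))

    lcs = [config.initial_Lc_nm]
    ruptures: list[float] = []  # rupture extension per branch
    truth_events: list[tuple[float, float]] = []
    fam_idx: list[int] = []
    x_prev = 0.0
    for _ in range(n_events):
        for _attempt in range(100):
            k, dlc, force = _draw_event(rng, config.families, weights)
            x_rup = wlc_inverse_extension(
                force, WLCParams(Lc_nm=lcs[-1], p_nm=config.p_nm), consts
            )
            # ruptures must advance along the extension axis
            if x_rup > x_prev + config.sample_step_nm:
                break
        else:
            raise RuntimeError("could not place a monotone rupture in 100 attempts")
        truth_events.append((dlc, force))
        fam_idx.append(k)
        ruptures.append(x_rup)
        lcs.append(lcs[-1] + dlc)
        x_prev = x_rup

    # detachment terminates the final branch (high-force family by default)
    if config.detachment:
        high = max(range(len(config.families)),
                   key=lambda i: config.families[i].force_mean_pN)
        fam = config.families[high]
        for _attempt in range(100):
            f_det = float(rng.normal(fam.force_mean_pN, fam.force_sd_pN))
            if f_det <= 0:
                continue
            x_det = wlc_inverse_extension(
                f_det, WLCParams(Lc_nm=lcs[-1], p_nm=config.p_nm), consts
            )
            if x_det > x_prev + config.sample_step_nm:
                break
        else:
            raise RuntimeError("could not place the detachment rupture")
        ruptures.append(x_det)
    else:
        ruptures.append(lcs[-1] * 0.9)

    x_end = ruptures[-1] + 5.0  # flat baseline tail after detachment
    x = np.arange(0.0, x_end, config.sample_step_nm)
    force = np.zeros_like(x)
    branch = 0
    for i, xi in enumerate(x):
        while branch < len(ruptures) and xi > ruptures[branch]:
            branch += 1
        if branch < len(lcs):
            params = WLCParams(Lc_nm=lcs[branch], p_nm=config.p_nm)
            if xi < params.Lc_nm:
                force[i] = wlc_force(float(xi), params, consts)

    if config.adhesion_peak:
        # non-specific tip-surface adhesion: sharp spike near zero extension
        f_adh = float(rng.uniform(60.0, 150.0))
        x_a = 2.0
        rise = x <= x_a
        fall = (x > x_a) & (x <= 2 * x_a)
        force[rise] += f_adh * x[rise] / x_a
        force[fall] += f_adh * (2 * x_a - x[fall]) / x_a

    if config.noise_sd_pN > 0:
        force = force + rng.normal(0.0, config.noise_sd_pN, size=x.size)

    tid = trace_id if trace_id is not None else f"synthetic-{seed}"
    trace = ForceExtensionTrace(
        extension_nm=x,
        force_pN=force,
        pulling_speed_nm_s=config.pulling_speed_nm_s,
        cantilever_k_N_m=config.cantilever_k_N_m,
        trace_id=tid,
        source="synthetic",
    )
    truth = TraceTruth(
        trace_id=tid,
        seed=seed,
        events=truth_events,
        family_index=fam_idx,
        total_Lc_nm=lcs[-1],
    )
    return trace, truth


def generate_ensemble(
    config: TraceGenConfig,
    n_traces: int,
    seed: int,
    consts: PhysicalConstants = PhysicalConstants(),
) -> tuple[list[ForceExtensionTrace], list[TraceTruth]]:
    """A set of independent seeded traces with pooled ground truth.

    All randomness flows from the single master seed through spawned
    per-trace seeds; the per-trace seed appears in each truth record.
    """
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_traces)]
    traces, truths = [], []
    for k, s in enumerate(child_seeds):
        tr, tt = generate_trace(config, s, trace_id=f"synthetic-{seed}-{k:04d}",
                                consts=consts)
        traces.append(tr)
        truths.append(tt)
    return traces, truths


# ---------------------------------------------------------------------------
# Toy structures


@dataclass(frozen=True)
class ToyStructureConfig:
    """Multi-domain β-meander toy protein for simulator tests.

    Each domain is a serpentine of straight strands (bead spacing σ =
    3.6 Å) separated by 5 Å, connected by single turn beads; domains stack
    along z with a short linker so that no native contacts cross domain
    boundaries.  ``contact_eps_scale`` softens or stiffens the contacts of
    individual domains.
    """

    n_domains: int = 1
    residues_per_domain: int = 30
    inter_domain_linker: int = 3
    strand_length: int = 7
    strand_spacing_A: float = 5.0
    bead_spacing_A: float = 3.6
    contact_eps_scale: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_domains < 1:
            raise ValueError("need at least one domain")
        if self.residues_per_domain < 2 * self.strand_length:
            raise ValueError("domains need at least two strands for contacts")


def _serpentine(n: int, cfg: ToyStructureConfig, origin: np.ndarray) -> np.ndarray:
    """β-meander path of n beads starting at ``origin`` in an xy-plane.

    Strand beads pleat alternately out of plane (as β-strands do) so that
    no three successive beads are collinear and every backbone torsion is
    well defined; the in-strand step is shortened so successive beads stay
    exactly σ apart.
    """
    sigma = cfg.bead_spacing_A
    dy = cfg.strand_spacing_A
    half = dy / 2.0
    dx_turn = float(np.sqrt(sigma**2 - half**2))
    pleat = 0.35  # out-of-plane amplitude, Å
    dx = float(np.sqrt(sigma**2 - (2 * pleat) ** 2))
    beads: list[np.ndarray] = []
    x, y = 0.0, 0.0
    direction = 1.0
    in_strand = 0
    zsign = 1.0
    while len(beads) < n:
        beads.append(np.array([x, y, zsign * pleat]))
        zsign = -zsign
        in_strand += 1
        if in_strand == cfg.strand_length and len(beads) < n:
            # single turn bead, then the next antiparallel strand
            dxt = float(np.sqrt(max(sigma**2 - half**2 - pleat**2, 0.1)))
            beads.append(np.array([x + direction * dxt, y + half, 0.0]))
            y += dy
            direction = -direction
            in_strand = 0
            zsign = 1.0
        else:
            x += direction * dx
    return np.array(beads[:n]) + origin


def generate_toy_structure(
    config: ToyStructureConfig,
) -> tuple[CGStructure, str]:
    """Build a toy Cα structure and its PDB text.

    Successive beads everywhere (strands, turns and inter-domain linkers)
    sit exactly σ = 3.6 Å apart; domains are stacked far enough apart that
    the Cα 8 Å contact criterion yields no cross-domain contacts.
    """
    sigma = config.bead_spacing_A
    z_step = (config.inter_domain_linker + 1) * sigma
    coords: list[np.ndarray] = []
    domain_ranges: dict[str, tuple[int, int]] = {}
    start = 1
    prev_end_xyz: np.ndarray | None = None
    for d in range(config.n_domains):
        if prev_end_xyz is None:
            origin = np.zeros(3)
        else:
            # linker climbs straight in z from the previous domain's last bead
            for k in range(1, config.inter_domain_linker + 1):
                coords.append(prev_end_xyz + np.array([0.0, 0.0, k * sigma]))
            start += config.inter_domain_linker
            # land the next domain's first (pleated) bead exactly σ above
            # the last linker bead
            origin = prev_end_xyz + np.array([0.0, 0.0, z_step - 0.35])
        dom = _serpentine(config.residues_per_domain, config, origin)
        coords.extend(dom)
        end = start + config.residues_per_domain - 1
        domain_ranges[f"SD{d + 1}"] = (start, end)
        start = end + 1
        prev_end_xyz = dom[-1]

    xyz = np.array(coords)
    d2 = np.linalg.norm(xyz[None, :, :] - xyz[:, None, :], axis=-1)
    np.fill_diagonal(d2, np.inf)
    if d2.min() < 2.0:
        raise ValueError("toy geometry collision: beads closer than 2 Å")

    structure = CGStructure(coords_A=xyz, chain_id="A", domain_ranges=domain_ranges)
    pdb_text = _calpha_pdb(xyz)
    return structure, pdb_text


def _calpha_pdb(xyz: np.ndarray, chain: str = "A") -> str:
    import gemmi

    st = gemmi.Structure()
    st.name = "toy"
    model = gemmi.Model("1")
    ch = gemmi.Chain(chain)
    for i, (x, y, z) in enumerate(xyz, start=1):
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(i, " ")
        res.het_flag = "A"
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(float(x), float(y), float(z))
        atom.occ = 1.0
        res.add_atom(atom)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    buf = st.make_pdb_string()
    return buf


# ---------------------------------------------------------------------------
# Truth fixture I/O


def write_truth_fixture(path: str | Path,
                        families: Sequence[EventFamily] | None = None) -> None:
    """Write the two-population ground-truth parameters as key=value text."""
    families = list(families) if families is not None else reference_truth_families()
    with Path(path).open("w") as fh:
        fh.write("#two-population (ΔLc, F) ground truth fixture\n")
        for k, fam in enumerate(families):
            for attr in ("dlc_mean_nm", "dlc_sd_nm", "force_mean_pN",
                         "force_sd_pN", "weight"):
                fh.write(f"family{k}.{attr}={getattr(fam, attr)!r}\n")


def read_truth_fixture(path: str | Path) -> list[EventFamily]:
    values: dict[int, dict[str, float]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        fam_part, _, attr = key.partition(".")
        k = int(fam_part.removeprefix("family"))
        values.setdefault(k, {})[attr] = float(val)
    return [EventFamily(**values[k]) for k in sorted(values)]
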