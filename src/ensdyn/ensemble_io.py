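"""Structure/trajectory input, residue equivalences and completeness filtering.

Reads PDB structures into chain records, establishes residue equivalences
across heterogeneous chains by sequence alignment (reference-anchored
multiple alignment over Cα-bearing residues), filters out chains with
unresolved residues in required regions, and assembles aligned coordinate
ensembles shared by every downstream stage.

Residue numbering convention: author numbering is preserved for reporting;
all internal computation uses 0-based alignment column indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1

__all__ = [
    "Residue",
    "ChainRecord",
    "EquivalenceMap",
    "CoordinateEnsemble",
    "read_structure",
    "build_equivalences",
    "filter_structures",
    "read_trajectory",
    "ensemble_from_chains",
    "write_ensemble_pdb",
    "write_exclusion_report",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Residue:
    """One amino-acid residue: author number, 3-letter name, atoms, B-factor."""

    number: int
    name: str
    ca: np.ndarray
    atoms: dict[str, np.ndarray] = field(default_factory=dict)
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        if self.ca.shape != (3,):
            raise ValueError("Cα position must be a 3-vector")
        self.atoms.setdefault("CA", self.ca)

    @property
    def one_letter(self) -> str:
        code = seq1(self.name.capitalize())
        return code if code.isalpha() else "X"


@dataclass
class ChainRecord:
    """An ordered protein chain plus its ligand (HETATM) annotations."""

    source_id: str
    residues: list[Residue]
    ligands: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        numbers = [r.number for r in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValueError(
                f"{self.source_id}: residue numbers must be strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float)


@dataclass
class EquivalenceMap:
    """Alignment columns and, per chain, the column → residue-index mapping.

    ``maps[source_id]`` is an integer array of length ``n_columns`` holding
    the residue index within that chain, or -1 where the chain has a gap.
    """

    n_columns: int
    maps: dict[str, np.ndarray]

    GAP = -1

    def __post_init__(self) -> None:
        for sid, m in self.maps.items():
            m = np.asarray(m, dtype=int)
            self.maps[sid] = m
            if m.shape != (self.n_columns,):
                raise ValueError(f"map for {sid} has wrong length")
            occupied = m[m >= 0]
            if len(np.unique(occupied)) != len(occupied):
                raise ValueError(f"map for {sid} is not invertible")

    def occupancy(self) -> np.ndarray:
        """Per column, the number of chains occupying it."""
        counts = np.zeros(self.n_columns, dtype=int)
        for m in self.maps.values():
            counts += m >= 0
        return counts

    def all_occupied(self) -> np.ndarray:
        """Columns occupied by every chain (the common analysis subset)."""
        return np.flatnonzero(self.occupancy() == len(self.maps))


@dataclass
class CoordinateEnsemble:
    """F aligned conformations over N equivalent positions.

    ``frames`` holds the Cα coordinates (F, N, 3) in Å; ``atom_frames``
    optionally carries additional named atoms (e.g. "CB") on the same grid,
    with NaN where an atom is absent (glycine Cβ).  ``labels`` are structure
    ids or times; when the frames are trajectory snapshots ``dt`` gives the
    frame spacing in ns.
    """

    frames: np.ndarray
    labels: list
    residue_numbers: np.ndarray | None = None
    residue_names: list[str] | None = None
    atom_frames: dict[str, np.ndarray] = field(default_factory=dict)
    regions: dict[str, np.ndarray] = field(default_factory=dict)
    bfactors: np.ndarray | None = None
    dt: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (F, N, 3)")
        if self.n_frames < 1 or self.n_positions < 3:
            raise ValueError("need F >= 1 frames and N >= 3 positions")
        if np.isnan(self.frames).any():
            raise ValueError("missing coordinates at retained positions")
        if len(self.labels) != self.n_frames:
            raise ValueError("one label per frame required")
        self.atom_frames.setdefault("CA", self.frames)
        if self.residue_numbers is not None:
            self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_positions(self) -> int:
        return self.frames.shape[1]

    def heavy_atom_names(self) -> list[str]:
        return sorted(self.atom_frames)

    def subset(self, columns: np.ndarray) -> "CoordinateEnsemble":
        """Restrict the ensemble to a subset of positions."""
        columns = np.asarray(columns, dtype=int)
        return CoordinateEnsemble(
            frames=self.frames[:, columns],
            labels=list(self.labels),
            residue_numbers=None if self.residue_numbers is None
            else self.residue_numbers[columns],
            residue_names=None if self.residue_names is None
            else [self.residue_names[c] for c in columns],
            atom_frames={k: v[:, columns] for k, v in self.atom_frames.items()},
            regions={},
            bfactors=None if self.bfactors is None else self.bfactors[columns],
            dt=self.dt,
        )


# ---------------------------------------------------------------------------
# Reading structures
# ---------------------------------------------------------------------------

_parser = PDBParser(QUIET=True)


def read_structure(path: str | Path,
                   chains: str | Sequence[str] | None = None,
                   model: int = 0) -> list[ChainRecord]:
    """Read one PDB file into a list of :class:`ChainRecord`.

    Parameters
    ----------
    path:
        PDB file to parse.
    chains:
        Chain identifier(s) to keep; ``None`` keeps all protein chains.
    model:
        Model index for multi-model files (crystal structures have one).

    Heteroatom residues (nucleotides, inhibitors, ions) are captured as
    ligand annotations ``(residue name, chain id)``, not as positions.
    Chains without any Cα are skipped with a warning.  Biopython's
    altloc handling keeps the highest-occupancy conformer.
    """
    path = Path(path)
    if isinstance(chains, str):
        chains = [chains]
    structure = _parser.get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no models found")
    mdl = models[model]

    records: list[ChainRecord] = []
    for chain in mdl:
        if chains is not None and chain.id not in chains:
            continue
        residues: list[Residue] = []
        ligands: list[tuple[str, str]] = []
        for res in chain:
            hetflag = res.id[0]
            if hetflag.strip():  # HETATM record (skip waters)
                if res.resname.strip() != "HOH":
                    ligands.append((res.resname.strip(), chain.id))
                continue
            if "CA" not in res:
                continue
            ca = res["CA"]
            atoms = {
                a.get_name(): np.array(a.get_coord(), dtype=float)
                for a in res
                if a.element != "H"
            }
            residues.append(Residue(
                number=res.id[1],
                name=res.resname.strip(),
                ca=np.array(ca.get_coord(), dtype=float),
                atoms=atoms,
                bfactor=float(ca.get_bfactor()),
            ))
        if not residues:
            if chains is None or chain.id in chains:
                warnings.warn(
                    f"{path.stem}_{chain.id}: no Cα atoms, chain skipped")
            continue
        records.append(ChainRecord(
            source_id=f"{path.stem}_{chain.id}",
            residues=residues,
            ligands=ligands,
        ))
    return records


# ---------------------------------------------------------------------------
# Residue equivalences
# ---------------------------------------------------------------------------

def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner


def _pairwise_map(aligner: Align.PairwiseAligner,
                  ref: str, other: str) -> tuple[dict[int, int], float]:
    """Map reference residue index → other residue index, plus identity."""
    aln = aligner.align(ref, other)[0]
    mapping: dict[int, int] = {}
    matches = 0
    aligned_ref, aligned_other = aln.aligned
    for (r0, r1), (o0, o1) in zip(aligned_ref, aligned_other):
        for k in range(r1 - r0):
            mapping[r0 + k] = o0 + k
            if ref[r0 + k] == other[o0 + k]:
                matches += 1
    identity = matches / max(len(ref), len(other))
    return mapping, identity


def build_equivalences(chains: Sequence[ChainRecord]) -> EquivalenceMap:
    """Establish residue equivalences across chains by sequence alignment.

    Each chain is globally aligned (BLOSUM62, affine gaps) to the first
    chain, which anchors the column set: every reference residue is one
    column, and residues of other chains inserted relative to the reference
    receive their own private trailing columns (they can never be occupied
    in all chains and therefore never enter the common subset).

    Chains whose best pairwise identity to the reference is below 30% are
    flagged with a warning for manual curation.
    """
    if len(chains) < 2:
        raise ValueError("need at least two chains to build equivalences")
    aligner = _aligner()
    ref = chains[0]
    ref_seq = ref.sequence
    n_ref = len(ref_seq)

    maps: dict[str, list[int]] = {ref.source_id: list(range(n_ref))}
    extra_columns: list[tuple[str, int]] = []  # (source_id, residue index)

    for chain in chains[1:]:
        mapping, identity = _pairwise_map(aligner, ref_seq, chain.sequence)
        if identity < 0.30:
            warnings.warn(
                f"{chain.source_id}: pairwise identity to reference "
                f"{identity:.0%} < 30%; flag for manual curation")
        col = [EquivalenceMap.GAP] * n_ref
        matched = set()
        for ref_i, oth_i in mapping.items():
            col[ref_i] = oth_i
            matched.add(oth_i)
        maps[chain.source_id] = col
        for i in range(len(chain.residues)):
            if i not in matched:
                extra_columns.append((chain.source_id, i))

    n_cols = n_ref + len(extra_columns)
    full: dict[str, np.ndarray] = {}
    for sid, col in maps.items():
        arr = np.full(n_cols, EquivalenceMap.GAP, dtype=int)
        arr[:len(col)] = col
        full[sid] = arr
    for j, (sid, res_i) in enumerate(extra_columns):
        full[sid][n_ref + j] = res_i
    return EquivalenceMap(n_columns=n_cols, maps=full)


# ---------------------------------------------------------------------------
# Completeness filter
# ---------------------------------------------------------------------------

def filter_structures(
    chains: Sequence[ChainRecord],
    eqmap: EquivalenceMap,
    required_regions: Mapping[str, Sequence[int]],
) -> tuple[list[ChainRecord], list[dict]]:
    """Keep only chains with resolved residues in every required region.

    A chain is retained iff every column of every required region maps to a
    residue of that chain.  Returns the retained chains and an exclusion
    report listing, per excluded chain, the first missing region and its
    missing columns.  Raises if nothing survives.
    """
    retained: list[ChainRecord] = []
    report: list[dict] = []
    for chain in chains:
        m = eqmap.maps[chain.source_id]
        missing = []
        for region, cols in required_regions.items():
            cols = np.asarray(cols, dtype=int)
            gap_cols = cols[m[cols] == EquivalenceMap.GAP]
            if gap_cols.size:
                missing.append((region, gap_cols.tolist()))
        if missing:
            report.append({
                "source_id": chain.source_id,
                "missing_regions": [r for r, _ in missing],
                "missing_columns": {r: c for r, c in missing},
            })
        else:
            retained.append(chain)
    if not retained:
        raise ValueError("completeness filter excluded every chain")
    return retained, report


def write_exclusion_report(report: list[dict], path: str | Path) -> None:
    """Write the exclusion report as TSV (structure id, missing regions)."""
    lines = ["source_id\tmissing_regions"]
    for row in report:
        lines.append(f"{row['source_id']}\t{','.join(row['missing_regions'])}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------

def ensemble_from_chains(
    chains: Sequence[ChainRecord],
    eqmap: EquivalenceMap,
    columns: np.ndarray | None = None,
) -> CoordinateEnsemble:
    """Assemble a coordinate ensemble from chains over shared columns.

    Defaults to the all-occupied column subset.  Carries Cα coordinates, a
    representative side-chain atom (Cβ where present) and Cα B-factors.
    """
    if columns is None:
        occ = np.zeros(eqmap.n_columns, dtype=int)
        for chain in chains:
            occ += eqmap.maps[chain.source_id] >= 0
        columns = np.flatnonzero(occ == len(chains))
    columns = np.asarray(columns, dtype=int)
    F, N = len(chains), len(columns)
    ca = np.empty((F, N, 3))
    cb = np.full((F, N, 3), np.nan)
    bf = np.empty((F, N))
    for f, chain in enumerate(chains):
        m = eqmap.maps[chain.source_id]
        for n, col in enumerate(columns):
            res = chain.residues[m[col]]
            ca[f, n] = res.ca
            bf[f, n] = res.bfactor
            if "CB" in res.atoms:
                cb[f, n] = res.atoms["CB"]
    ref_map = eqmap.maps[chains[0].source_id]
    numbers = np.array([chains[0].residues[ref_map[c]].number
                        for c in columns])
    names = [chains[0].residues[ref_map[c]].name for c in columns]
    return CoordinateEnsemble(
        frames=ca,
        labels=[c.source_id for c in chains],
        residue_numbers=numbers,
        residue_names=names,
        atom_frames={"CA": ca, "CB": cb},
        bfactors=bf.mean(axis=0),
    )


def read_trajectory(
    topology: str | Path | None,
    trajectory: str | Path,
    stride: int = 1,
    dt: float | None = None,
) -> CoordinateEnsemble:
    """Read a trajectory into a coordinate ensemble.

    Multi-model PDB is always supported (``topology`` may be ``None``);
    DCD is supported through MDAnalysis when that reader is importable —
    a declared capability, raising a clear error otherwise.  ``dt`` is the
    frame spacing in ns of the *input* file; the returned ensemble stores
    ``dt * stride``.
    """
    trajectory = Path(trajectory)
    if trajectory.suffix.lower() == ".dcd":
        return _read_dcd(topology, trajectory, stride, dt)
    structure = _parser.get_structure(trajectory.stem, str(trajectory))
    frames_ca: list[np.ndarray] = []
    frames_cb: list[np.ndarray] = []
    names: list[str] = []
    numbers: list[int] = []
    n_atoms_ref: int | None = None
    for i, mdl in enumerate(structure):
        if i % stride:
            continue
        ca, cb, nm, nb, n_atoms = [], [], [], [], 0
        for chain in mdl:
            for res in chain:
                if res.id[0].strip() or "CA" not in res:
                    continue
                n_atoms += len(res)
                ca.append(np.array(res["CA"].get_coord(), dtype=float))
                cb.append(np.array(res["CB"].get_coord(), dtype=float)
                          if "CB" in res else np.full(3, np.nan))
                nm.append(res.resname.strip())
                nb.append(res.id[1])
        if n_atoms_ref is None:
            n_atoms_ref, names, numbers = n_atoms, nm, nb
        elif n_atoms != n_atoms_ref:
            raise ValueError(
                f"atom count mismatch: model 0 has {n_atoms_ref}, "
                f"model {i} has {n_atoms}")
        frames_ca.append(np.array(ca))
        frames_cb.append(np.array(cb))
    if not frames_ca:
        raise ValueError(f"{trajectory}: no frames read")
    eff_dt = None if dt is None else dt * stride
    times = (list(range(0, len(structure), stride)) if dt is None
             else [round(i * dt, 9) for i in range(0, len(structure), stride)])
    ca_arr = np.stack(frames_ca)
    return CoordinateEnsemble(
        frames=ca_arr,
        labels=times[:len(frames_ca)],
        residue_numbers=np.array(numbers),
        residue_names=names,
        atom_frames={"CA": ca_arr, "CB": np.stack(frames_cb)},
        dt=eff_dt,
    )


def _read_dcd(topology, trajectory, stride, dt):
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - capability declaration
        raise RuntimeError(
            "DCD reading requires MDAnalysis, which is not importable"
        ) from exc
    if topology is None:
        raise ValueError("DCD trajectories require a topology file")
    u = mda.Universe(str(topology), str(trajectory))
    ca_sel = u.select_atoms("name CA")
    cb_sel = u.select_atoms("name CB")
    if len(u.atoms) == 0:
        raise ValueError("empty topology")
    cb_res = {r.resindex for r in cb_sel.residues}
    frames_ca, frames_cb, times = [], [], []
    for i, ts in enumerate(u.trajectory):
        if i % stride:
            continue
        frames_ca.append(ca_sel.positions.astype(float).copy())
        cb = np.full((len(ca_sel), 3), np.nan)
        j = 0
        for k, res in enumerate(ca_sel.residues):
            if res.resindex in cb_res:
                cb[k] = cb_sel.positions[j]
                j += 1
        frames_cb.append(cb)
        times.append(i * (dt or 1.0))
    ca_arr = np.stack(frames_ca)
    return CoordinateEnsemble(
        frames=ca_arr,
        labels=times,
        residue_numbers=np.array([r.resid for r in ca_sel.residues]),
        residue_names=[r.resname for r in ca_sel.residues],
        atom_frames={"CA": ca_arr, "CB": np.stack(frames_cb)},
        dt=None if dt is None else dt * stride,
    )


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

_PDB_ATOM = ("ATOM  {serial:>5d} {name:^4s}{alt:1s}{res:>3s} {chain:1s}"
             "{resseq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
             "{occ:6.2f}{b:6.2f}          {element:>2s}\n")


def write_ensemble_pdb(ensemble: CoordinateEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB (one MODEL per frame).

    Coordinates are written at the format's 0.001 Å precision, which bounds
    the round-trip error of :func:`read_trajectory`.
    """
    names = ensemble.residue_names or ["ALA"] * ensemble.n_positions
    numbers = (ensemble.residue_numbers
               if ensemble.residue_numbers is not None
               else np.arange(1, ensemble.n_positions + 1))
    atom_names = [a for a in ("CA", "CB") if a in ensemble.atom_frames]
    with open(path, "w") as fh:
        for f in range(ensemble.n_frames):
            fh.write(f"MODEL     {f + 1:>4d}\n")
            serial = 1
            for n in range(ensemble.n_positions):
                for aname in atom_names:
                    xyz = ensemble.atom_frames[aname][f, n]
                    if np.isnan(xyz).any():
                        continue
                    fh.write(_PDB_ATOM.format(
                        serial=serial, name=f" {aname}", alt=" ",
                        res=names[n][:3], chain="A",
                        resseq=int(numbers[n]), icode=" ",
                        x=xyz[0], y=xyz[1], z=xyz[2],
                        occ=1.0, b=0.0, element=aname[0]))
                    serial += 1
            fh.write("TER\nENDMDL\n")
        fh.write("END\n")
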