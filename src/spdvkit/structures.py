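"""Structure reading and sequence-to-structure residue mapping.

Coordinates are Cα positions in Å. Human positions are 1-based positions in
the reference (UniProt) protein sequence; structure residues keep the author
numbering of the deposited file. All cross-referencing between the two
numbering systems goes through :class:`ResidueMap`, built from a pairwise
alignment of the human sequence against the modelled chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

#: residue key: (chain_id, author residue number, insertion code)
ResidueKey = tuple[str, int, str]


@dataclass
class Residue:
    """One polymer residue; ``ca`` is None when no Cα atom is resolved."""

    chain_id: str
    number: int
    icode: str
    name: str  # 3-letter code, upper case
    ca: np.ndarray | None

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.number, self.icode)

    @property
    def one_letter(self) -> str:
        """1-letter amino-acid code; nonstandard residues translate to their
        parent amino acid where known, else 'X'."""
        info = gemmi.find_tabulated_residue(self.name)
        if info is None:
            return "X"
        code = info.one_letter_code.upper()
        return code if code.isalpha() else "X"


@dataclass
class StructureModel:
    """Resolved residues of a protein structure with Cα coordinates."""

    structure_id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("StructureModel requires at least one residue")
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate residue keys in structure")
        self._by_key = {r.key: r for r in self.residues}

    def __getitem__(self, key: ResidueKey) -> Residue:
        return self._by_key[key]

    def __contains__(self, key: ResidueKey) -> bool:
        return key in self._by_key

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain_id, None)
        return list(seen)

    def chain(self, chain_id: str) -> list[Residue]:
        out = [r for r in self.residues if r.chain_id == chain_id]
        if not out:
            raise KeyError(f"no chain {chain_id!r}; available: {self.chain_ids}")
        return out

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter for r in self.chain(chain_id))

    def ca_coords(self, keys: Iterable[ResidueKey] | None = None) -> tuple[list[ResidueKey], np.ndarray]:
        """Keys and an (n, 3) array for residues that have a Cα."""
        res = self.residues if keys is None else [self._by_key[k] for k in keys]
        with_ca = [r for r in res if r.ca is not None]
        if not with_ca:
            return [], np.empty((0, 3))
        return [r.key for r in with_ca], np.vstack([r.ca for r in with_ca])


def _residues_from_gemmi(st: gemmi.Structure, chains: Sequence[str] | None) -> list[Residue]:
    st.setup_entities()
    model = st[0]
    available = [ch.name for ch in model]
    if chains is not None:
        missing = [c for c in chains if c not in available]
        if missing:
            raise KeyError(f"chain(s) {missing} not found; available chains: {available}")
    residues: list[Residue] = []
    for ch in model:
        if chains is not None and ch.name not in chains:
            continue
        for res in ch:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            ca = None
            for atom in res:
                # first-listed altLoc wins; guards against Ca2+ ions named CA
                if atom.name == "CA" and atom.element.name == "C":
                    ca = np.array([atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)
                    break
            if ca is not None and not np.all(np.isfinite(ca)):
                raise ValueError(f"non-finite Cα coordinates at {ch.name}/{res.seqid}")
            icode = res.seqid.icode.strip() if res.seqid.icode else ""
            residues.append(Residue(ch.name, res.seqid.num, icode, res.name.upper(), ca))
    return residues


def read_structure(
    path: str | Path,
    format: str | None = None,
    chains: Sequence[str] | None = None,
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Parameters
    ----------
    path
        Structure file; the format is inferred from the extension unless
        ``format`` is one of ``"pdb"`` / ``"mmcif"``.
    chains
        Optional chain filter (author chain ids). An empty or unmatched
        selection raises a ``KeyError`` naming the available chains.

    Residues lacking a Cα atom are retained with ``ca=None``. Only amino-acid
    residues (including nonstandard ones such as MSE) are kept.
    """
    path = Path(path)
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format in ("mmcif", "cif"):
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, IndexError) as exc:
        raise ValueError(f"could not parse structure file {path}: {exc}") from exc
    residues = _residues_from_gemmi(st, chains)
    if not residues:
        raise ValueError(f"no amino-acid residues read from {path}")
    return StructureModel(st.name or path.stem, residues)


def read_pdb_string(text: str, structure_id: str = "synthetic", chains: Sequence[str] | None = None) -> StructureModel:
    """Parse PDB-format text (used so generated structures go through the
    same reader as deposited files)."""
    st = gemmi.read_pdb_string(text)
    residues = _residues_from_gemmi(st, chains)
    if not residues:
        raise ValueError("no amino-acid residues in PDB text")
    return StructureModel(structure_id, residues)


def pdb_text(structure: StructureModel) -> str:
    """Render a StructureModel as minimal PDB-format text (Cα atoms only)."""
    lines = []
    serial = 0
    for r in structure.residues:
        if r.ca is None:
            continue
        serial += 1
        x, y, z = r.ca
        lines.append(
            f"ATOM  {serial:5d}  CA  {r.name:<3s} {r.chain_id:1s}{r.number:4d}{r.icode or ' ':1s}"
            f"   {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pdb(structure: StructureModel, path: str | Path) -> None:
    Path(path).write_text(pdb_text(structure))


@dataclass
class MapEntry:
    human_pos: int
    human_aa: str
    chain_id: str
    struct_key: ResidueKey
    struct_aa: str
    mismatch: bool


@dataclass
class ResidueMap:
    """Bijection between 1-based human sequence positions and structure residues.

    ``unmapped`` holds (human_pos, reason) pairs with reason one of ``gap``
    (aligned to a gap, e.g. a disordered/absent residue), ``unresolved``
    (residue modelled but without a Cα) or ``nonstandard`` (no parent amino
    acid known).
    """

    chain_id: str
    entries: list[MapEntry]
    unmapped: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        pos = [e.human_pos for e in self.entries]
        if pos != sorted(pos) or len(set(pos)) != len(pos):
            raise ValueError("entries must be strictly increasing in human_pos")
        overlap = set(pos) & {p for p, _ in self.unmapped}
        if overlap:
            raise ValueError(f"positions both mapped and unmapped: {sorted(overlap)}")
        self._by_pos = {e.human_pos: e for e in self.entries}
        self._by_key = {e.struct_key: e for e in self.entries}

    def key_for(self, human_pos: int) -> ResidueKey:
        return self._by_pos[human_pos].struct_key

    def pos_for(self, key: ResidueKey) -> int:
        return self._by_key[key].human_pos

    def __contains__(self, human_pos: int) -> bool:
        return human_pos in self._by_pos

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "human_pos": e.human_pos,
                "human_aa": e.human_aa,
                "chain": e.chain_id,
                "struct_resnum": f"{e.struct_key[1]}{e.struct_key[2]}",
                "struct_aa": e.struct_aa,
                "status": "mismatch" if e.mismatch else "mapped",
            }
            for e in self.entries
        ]
        rows += [
            {"human_pos": p, "human_aa": "", "chain": self.chain_id,
             "struct_resnum": "", "struct_aa": "", "status": reason}
            for p, reason in self.unmapped
        ]
        return pd.DataFrame(rows).sort_values("human_pos", ignore_index=True)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_pairwise_fasta(path: str | Path) -> tuple[str, str]:
    """Read a 2-record FASTA pairwise alignment (human row first)."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"pairwise alignment must have exactly 2 records, got {len(records)}")
    return str(records[0].seq).upper(), str(records[1].seq).upper()


def build_residue_map(
    human_seq: str,
    alignment: tuple[str, str],
    structure: StructureModel,
    chain_id: str,
) -> ResidueMap:
    """Map human sequence positions onto a structure chain via a pairwise alignment.

    The alignment is (human row, structure row), equal gapped lengths; the
    ungapped human row must reproduce ``human_seq`` and the ungapped structure
    row the chain's modelled residue sequence. Aligned mismatches (ortholog
    substitutions) are recorded but still mapped; human positions aligned to
    gaps or to residues without a Cα go to ``unmapped``.
    """
    human_row, struct_row = (alignment[0].upper(), alignment[1].upper())
    if len(human_row) != len(struct_row):
        raise ValueError(
            f"alignment rows differ in length: {len(human_row)} vs {len(struct_row)}"
        )
    human_seq = human_seq.upper()
    ungapped_h = human_row.replace("-", "")
    if ungapped_h != human_seq:
        col = next(
            (i for i, (a, b) in enumerate(zip(ungapped_h, human_seq)) if a != b),
            min(len(ungapped_h), len(human_seq)),
        )
        raise ValueError(
            f"ungapped human alignment row does not reproduce human_seq "
            f"(first difference at sequence position {col + 1})"
        )
    chain_res = structure.chain(chain_id)
    chain_seq = "".join(r.one_letter for r in chain_res)
    ungapped_s = struct_row.replace("-", "")
    if ungapped_s != chain_seq:
        col = next(
            (i for i, (a, b) in enumerate(zip(ungapped_s, chain_seq)) if a != b),
            min(len(ungapped_s), len(chain_seq)),
        )
        raise ValueError(
            f"ungapped structure alignment row does not match chain {chain_id} "
            f"sequence (first difference at chain residue index {col + 1})"
        )

    entries: list[MapEntry] = []
    unmapped: list[tuple[int, str]] = []
    hpos = 0
    sidx = 0
    for a, b in zip(human_row, struct_row):
        if a != "-":
            hpos += 1
        if b != "-":
            res = chain_res[sidx]
            sidx += 1
        if a == "-":
            continue
        if b == "-":
            unmapped.append((hpos, "gap"))
            continue
        if res.one_letter == "X":
            unmapped.append((hpos, "nonstandard"))
        elif res.ca is None:
            unmapped.append((hpos, "unresolved"))
        else:
            entries.append(MapEntry(hpos, a, chain_id, res.key, res.one_letter, mismatch=a != res.one_letter))
    return ResidueMap(chain_id, entries, unmapped)


def map_variants(
    variants: pd.DataFrame, residue_map: ResidueMap
) -> tuple[list[ResidueKey], pd.DataFrame]:
    """Resolve variant positions to structure residues.

    Multiple variants at one position collapse to one unique site. Returns the
    unique mapped site keys (in order of first occurrence) and a report of
    variants that could not be placed, with the reason.

    Raises ``ValueError`` when a variant's reference residue disagrees with
    the mapped human sequence letter at that position.
    """
    unmapped_reasons = dict(residue_map.unmapped)
    offenders = []
    sites: list[ResidueKey] = []
    seen: set[ResidueKey] = set()
    report_rows = []
    for row in variants.itertuples(index=False):
        pos = int(row.human_pos)
        if pos in residue_map:
            entry = residue_map._by_pos[pos]
            if getattr(row, "ref_aa", entry.human_aa) != entry.human_aa:
                offenders.append(f"p.{row.ref_aa}{pos}{row.alt_aa} (sequence has {entry.human_aa})")
                continue
            if entry.struct_key not in seen:
                seen.add(entry.struct_key)
                sites.append(entry.struct_key)
        else:
            reason = unmapped_reasons.get(pos, "outside_map")
            report_rows.append({"human_pos": pos,
                               "ref_aa": getattr(row, "ref_aa", ""),
                               "alt_aa": getattr(row, "alt_aa", ""),
                               "reason": reason})
    if offenders:
        raise ValueError("variant reference residues disagree with sequence: " + "; ".join(offenders))
    report = pd.DataFrame(report_rows, columns=["human_pos", "ref_aa", "alt_aa", "reason"])
    return sites, report
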