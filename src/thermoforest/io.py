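"""Readers and writers for every external format the tool touches.

Formats: FASTA, PSI-BLAST ASCII PSSM, PDB (Ca extraction), DSSP output,
a 3-column predicted-annotation TSV (position, ss3, rsa), and the mutation
table TSV (columns: protein_id, mutations, ddg[, direction, pair_id]).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import AMINO_ACIDS, PSSM_AA_ORDER
from .records import (
    MutationDataset,
    MutationRecord,
    ParseError,
    ProteinRecord,
    Pssm,
    Substitution,
    ValidationError,
)

# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------
# Parsed by hand (not Bio.SeqIO) so parse errors can name the offending line.


def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects (order preserved)."""
    records: list[ProteinRecord] = []
    header, chunks, header_line = None, [], 0

    def flush(lineno):
        if header is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise ParseError(f"{path}:{header_line}: entry {header!r} has an empty sequence")
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise ParseError(
                f"{path}:{header_line}: entry {header!r} contains non-standard "
                f"residue(s) {sorted(bad)}"
            )
        records.append(ProteinRecord(id=header, sequence=seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ParseError(f"{path}:{lineno}: sequence data before any header")
                chunks.append(line)
        flush(lineno if records or header else 0)
    return records


def write_fasta(path, proteins) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------


def read_pssm_ascii(path, sequence: str | None = None) -> Pssm:
    """Parse a PSI-BLAST ASCII PSSM (log-odds + weighted-percentage blocks).

    If ``sequence`` is given, the residue column of every row is checked
    against it.
    """
    aa_order = None
    log_odds, weighted, residues = [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            fields = raw.split()
            if aa_order is None:
                # Column-header line: 40 single letters (two 20-column blocks).
                if len(fields) == 40 and all(len(f) == 1 for f in fields):
                    first, second = fields[:20], fields[20:]
                    if first != second:
                        raise ParseError(f"{path}:{lineno}: mismatched PSSM column blocks")
                    aa_order = "".join(first)
                continue
            if len(fields) < 2 or not fields[0].isdigit():
                break  # footer (Lambda/K statistics) or blank line: matrix ended
            if len(fields) < 42:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 42 columns in PSSM row, got {len(fields)}"
                )
            try:
                lo = [int(x) for x in fields[2:22]]
                wt = [float(x) for x in fields[22:42]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric PSSM entry ({exc})") from None
            residues.append(fields[1])
            log_odds.append(lo)
            weighted.append(wt)
    if aa_order is None or not log_odds:
        raise ParseError(f"{path}: no PSSM matrix found")
    if sequence is not None:
        found = "".join(residues)
        if found != sequence:
            raise ValidationError(
                f"{path}: PSSM residue column disagrees with the attached sequence"
            )
    pssm = Pssm(np.array(log_odds), np.array(weighted), aa_order=aa_order)
    return _reorder_pssm(pssm)


def _reorder_pssm(pssm: Pssm) -> Pssm:
    """Normalise column order to :data:`PSSM_AA_ORDER`."""
    if pssm.aa_order == PSSM_AA_ORDER:
        return pssm
    idx = [pssm.aa_order.index(a) for a in PSSM_AA_ORDER]
    return Pssm(pssm.log_odds[:, idx], pssm.weighted[:, idx], aa_order=PSSM_AA_ORDER)


def write_pssm_ascii(path, sequence: str, pssm: Pssm) -> None:
    """Write a PSSM in the standard two-block ASCII layout."""
    cols = "  ".join(PSSM_AA_ORDER)
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed, weighted "
                 "observed percentages rounded down\n")
        fh.write(f"           {cols}   {cols}\n")
        for i, aa in enumerate(sequence):
            lo = " ".join(f"{int(v):3d}" for v in pssm.log_odds[i])
            wt = " ".join(f"{int(round(v)):3d}" for v in pssm.weighted[i])
            fh.write(f"{i + 1:5d} {aa}  {lo}  {wt}  0.00 0.00\n")
        fh.write("\n")


# ---------------------------------------------------------------------------
# Structures: PDB Ca extraction, DSSP output
# ---------------------------------------------------------------------------


class EmptyStructureError(ValueError):
    pass


def read_pdb_ca(path, chain: str | None = None) -> np.ndarray:
    """Extract Ca coordinates from the first model of a PDB file.

    One configured chain (default: the only chain, error if ambiguous);
    altloc blank or 'A'; insertion codes rejected. Residues with no Ca atom
    get a NaN row (flagged gap).
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("s", str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise EmptyStructureError(f"{path}: no models") from None
    chains = {c.id: c for c in model}
    if chain is None:
        if len(chains) != 1:
            raise ValidationError(
                f"{path}: {len(chains)} chains present; specify one of {sorted(chains)}"
            )
        chain_obj = next(iter(chains.values()))
    else:
        if chain not in chains:
            raise ValidationError(f"{path}: chain {chain!r} not found")
        chain_obj = chains[chain]

    coords = []
    for residue in chain_obj:
        hetflag, _resseq, icode = residue.id
        if hetflag != " ":
            continue
        if icode != " ":
            raise ValidationError(f"{path}: insertion code {icode!r} not supported")
        ca = residue.child_dict.get("CA")
        if ca is None:
            coords.append([np.nan] * 3)
            continue
        if ca.is_disordered():
            ca = ca.disordered_get("A")
        coords.append(ca.coord.tolist())
    arr = np.asarray(coords, dtype=float)
    if arr.size == 0 or np.all(np.isnan(arr)):
        raise EmptyStructureError(f"{path}: no Ca atoms found")
    return arr


def read_dssp(path, chain: str | None = None) -> tuple[list[str], np.ndarray]:
    """Read a DSSP output file; return per-residue 8-state SS codes and ASA (A^2).

    Chain-break rows are skipped by the parser (they carry no residue); the
    caller aligns DSSP rows to the sequence by order.
    """
    from Bio.PDB.DSSP import make_dssp_dict

    dssp_dict, keys = make_dssp_dict(str(path))
    ss8, asa = [], []
    for key in keys:
        key_chain = key[0]
        if chain is not None and key_chain != chain:
            continue
        aa, ss, acc = dssp_dict[key][:3]
        ss8.append(ss if ss.strip() else "-")
        asa.append(float(acc))
    if not ss8:
        raise EmptyStructureError(f"{path}: no DSSP residue rows" +
                                  (f" for chain {chain!r}" if chain else ""))
    return ss8, np.asarray(asa)


# ---------------------------------------------------------------------------
# Predicted annotation TSV (sequence mode): position, ss3, rsa
# ---------------------------------------------------------------------------


def read_annotation_tsv(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"position", "ss3", "rsa"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: annotation TSV needs columns {sorted(required)}")
    df = df.sort_values("position")
    if list(df["position"]) != list(range(1, len(df) + 1)):
        raise ParseError(f"{path}: annotation positions must be 1..L without gaps")
    ss3 = [str(s) for s in df["ss3"]]
    if any(s not in ("H", "E", "C") for s in ss3):
        raise ParseError(f"{path}: ss3 values must be H/E/C")
    return ss3, df["rsa"].to_numpy(dtype=float)


def write_annotation_tsv(path, ss3, rsa) -> None:
    with open(path, "w") as fh:
        fh.write("position\tss3\trsa\n")
        for i, (s, r) in enumerate(zip(ss3, rsa), start=1):
            fh.write(f"{i}\t{s}\t{float(r)!r}\n")


# ---------------------------------------------------------------------------
# Mutation table TSV
# ---------------------------------------------------------------------------


def read_mutation_table(path, proteins: dict[str, ProteinRecord],
                        negate_ddg: bool = False) -> MutationDataset:
    """Read a mutation TSV into a validated forward dataset.

    ``negate_ddg`` flips the sign column for sources using the opposite
    convention (this package: positive = stabilizing). This is the single
    place in the package where the sign convention is applied.
    """
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip",
                     dtype={"protein_id": str, "mutations": str})
    required = {"protein_id", "mutations", "ddg"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: mutation TSV needs columns {sorted(required)}")
    has_direction = "direction" in df.columns
    records = []
    for row in df.itertuples(index=False):
        subs = tuple(Substitution.parse(s) for s in str(row.mutations).split(","))
        ddg = float(row.ddg)
        rec = MutationRecord(
            protein_id=str(row.protein_id),
            subs=subs,
            ddg=-ddg if negate_ddg else ddg,
            direction=getattr(row, "direction", "forward") if has_direction else "forward",
            pair_id=str(getattr(row, "pair_id", "") or ""),
        )
        records.append(rec)
    ds = MutationDataset(records=records, proteins=dict(proteins))
    ds.validate()
    return ds


def write_mutation_table(path, dataset: MutationDataset) -> None:
    """Write a mutation TSV; floats use repr so a read-back is bit-exact."""
    with open(path, "w") as fh:
        fh.write("protein_id\tmutations\tddg\tdirection\tpair_id\n")
        for rec in dataset.records:
            fh.write(
                f"{rec.protein_id}\t{rec.mutation_string()}\t{float(rec.ddg)!r}"
                f"\t{rec.direction}\t{rec.pair_id}\n"
            )


def write_ca_pdb(path, protein: ProteinRecord, chain: str = "A") -> None:
    """Write a Ca-only PDB file (ATOM records) for a protein with coordinates."""
    from Bio.SeqUtils import seq3

    if protein.ca_coords is None:
        raise ValidationError(f"protein {protein.id!r} has no coordinates")
    with open(path, "w") as fh:
        for i, (aa, xyz) in enumerate(zip(protein.sequence, protein.ca_coords), start=1):
            if np.any(np.isnan(xyz)):
                continue
            resname = seq3(aa).upper()
            fh.write(
                f"ATOM  {i:5d}  CA  {resname} {chain}{i:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
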