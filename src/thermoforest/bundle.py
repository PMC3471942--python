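"""On-disk bundle layout tying all input formats together.

A *bundle* is a directory holding everything one study needs::

    bundle/
      proteins.fasta          wild-type sequences
      pssm/<id>.pssm          PSI-BLAST ASCII profile per protein
      ann/<id>.tsv            predicted/derived ss3+rsa per protein
      pdb/<id>.pdb            Ca-only coordinates (structure mode)
      mutations.tsv           protein_id, mutations, ddg
      tables/seq_<kind>_<state>.tsv   sequential potential tables
      tables/dt_<kind>_<state>.tsv    spatial potential tables (structure mode)
      truth.json              planted ground truth (synthetic bundles only)

The CLI's subcommands all operate on this layout; the library functions
accept in-memory objects directly.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import io as tio
from .delaunay import DT_FRAG_FEATURES
from .fragments import SEQ_FRAG_FEATURES, PotentialTable
from .pipeline import FeaturePipeline
from .records import MutationDataset, ValidationError


def _table_name(prefix: str, kind: str, state: str | None) -> str:
    return f"{prefix}_{kind}_{state if state is not None else 'all'}.tsv"


def write_tables(out_dir, tables, prefix: str) -> None:
    out = tio.ensure_dir(out_dir)
    for (kind, state), table in tables.items():
        table.to_tsv(out / _table_name(prefix, kind, state))


def read_tables(table_dir, prefix: str, keys) -> dict:
    tables = {}
    for kind, state in keys:
        path = Path(table_dir) / _table_name(prefix, kind, state)
        if not path.exists():
            raise ValidationError(f"missing potential table file {path}")
        tables[(kind, state)] = PotentialTable.from_tsv(path)
    return tables


def write_bundle(out_dir, dataset: MutationDataset, tables, dt_tables=None,
                 truth: dict | None = None) -> Path:
    out = tio.ensure_dir(out_dir)
    proteins = list(dataset.proteins.values())
    tio.write_fasta(out / "proteins.fasta", proteins)
    tio.ensure_dir(out / "pssm")
    tio.ensure_dir(out / "ann")
    for p in proteins:
        if p.profile is not None:
            tio.write_pssm_ascii(out / "pssm" / f"{p.id}.pssm", p.sequence, p.profile)
        if p.ss is not None and p.rsa is not None:
            tio.write_annotation_tsv(out / "ann" / f"{p.id}.tsv", p.ss, p.rsa)
        if p.ca_coords is not None:
            tio.ensure_dir(out / "pdb")
            tio.write_ca_pdb(out / "pdb" / f"{p.id}.pdb", p)
    tio.write_mutation_table(out / "mutations.tsv", dataset)
    write_tables(out / "tables", tables, "seq")
    if dt_tables:
        write_tables(out / "tables", dt_tables, "dt")
    if truth is not None:
        (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return out


def load_bundle(bundle_dir, mode: str = "sequence"
                ) -> tuple[MutationDataset, FeaturePipeline]:
    bundle = Path(bundle_dir)
    proteins = {}
    for p in tio.read_fasta(bundle / "proteins.fasta"):
        pssm_path = bundle / "pssm" / f"{p.id}.pssm"
        ann_path = bundle / "ann" / f"{p.id}.tsv"
        pdb_path = bundle / "pdb" / f"{p.id}.pdb"
        layers = {}
        if pssm_path.exists():
            layers["profile"] = tio.read_pssm_ascii(pssm_path, sequence=p.sequence)
        if ann_path.exists():
            ss3, rsa = tio.read_annotation_tsv(ann_path)
            layers["ss"], layers["rsa"] = ss3, rsa
        if mode == "structure":
            if not pdb_path.exists():
                raise ValidationError(f"structure mode: missing {pdb_path}")
            layers["ca_coords"] = tio.read_pdb_ca(pdb_path, chain="A")
        proteins[p.id] = p.attach(**layers)

    tables = read_tables(bundle / "tables", "seq", SEQ_FRAG_FEATURES.values())
    dt_tables = None
    if mode == "structure":
        dt_tables = read_tables(bundle / "tables", "dt", DT_FRAG_FEATURES.values())
    dataset = tio.read_mutation_table(bundle / "mutations.tsv", proteins)
    pipeline = FeaturePipeline(tables=tables, dt_tables=dt_tables, mode=mode)
    return dataset, pipeline
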