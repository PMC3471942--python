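"""Synthetic fixtures: proteins, structures, profiles, corpora and mutation
datasets with a planted anti-symmetric ddG signal.

The generator stands in for curated experimental mutation collections: it
produces every input the pipeline consumes (FASTA sequences, idealised Ca
traces, PSI-BLAST-style profiles, per-residue annotations, potential-table
corpora, mutation tables) with known ground truth. The planted ddG is a
linear combination of *difference-type* features plus Gaussian noise, so the
ground truth is exactly anti-symmetric under the forward/reverse swap — the
thermodynamic identity the evaluation protocol is built on.

All randomness flows through one explicitly passed numpy Generator (or an
integer seed); there is no global state, so every fixture is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import BACKGROUND_FREQUENCIES, PSSM_AA_ORDER
from .annotations import residue_states
from .fragments import build_sequence_tables
from .pipeline import DIFFERENCE_FEATURES, FeaturePipeline
from .records import (
    MutationDataset,
    MutationRecord,
    ProteinRecord,
    Pssm,
    Substitution,
    ValidationError,
)

#: Default planted weights (all difference-type features; see DIFFERENCE_FEATURES).
DEFAULT_PLANTED_WEIGHTS = {
    "POSI": 40.0,
    "TINY": -30.0,
    "dASA": 0.2,
    "pIa": 60.0,
    "FBocc": 1.5,
}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class PlantedModel:
    """Ground truth for synthetic ddG: ddg = sum(weights * features) + noise."""

    weights: dict[str, float]
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        bad = set(self.weights) - set(DIFFERENCE_FEATURES)
        if bad:
            raise ValidationError(
                f"planted weights must reference difference-type features; bad: {sorted(bad)}"
            )

    def signal(self, features: dict[str, float]) -> float:
        return sum(w * features[name] for name, w in self.weights.items())


# ---------------------------------------------------------------------------
# Proteins, structures, profiles
# ---------------------------------------------------------------------------


def gen_sequence(length: int, rng, frequencies=BACKGROUND_FREQUENCIES) -> str:
    letters = sorted(frequencies)
    probs = np.array([frequencies[a] for a in letters])
    probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=length, p=probs))


def gen_protein(length: int, seed, id: str = "synth") -> ProteinRecord:
    """Random protein with background residue frequencies."""
    if length < 10:
        raise ValidationError(f"length must be >= 10, got {length}")
    rng = _rng(seed)
    return ProteinRecord(id=id, sequence=gen_sequence(length, rng))


def _helix_coords(n: int) -> np.ndarray:
    """Ideal Ca helix: rise 1.5 A, radius 2.3 A, 100 degrees per residue."""
    theta = np.deg2rad(100.0) * np.arange(n)
    return np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * np.arange(n)])


def _walk_coords(n: int, rng, step: float = 3.8, min_dist: float = 3.5) -> np.ndarray:
    """Self-avoiding random chain with fixed Ca-Ca step length."""
    coords = [np.zeros(3)]
    while len(coords) < n:
        for _ in range(200):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            candidate = coords[-1] + step * direction
            prior = np.array(coords[:-1]) if len(coords) > 1 else None
            if prior is None or np.min(np.linalg.norm(prior - candidate, axis=1)) >= min_dist:
                coords.append(candidate)
                break
        else:  # chain trapped: restart from scratch (rare at these sizes)
            coords = [np.zeros(3)]
    return np.asarray(coords)


def gen_structure(protein: ProteinRecord, motif: str = "helix", seed=0) -> ProteinRecord:
    """Attach idealised coordinates plus ss3/rsa annotation.

    ``helix``: ideal Ca helix labelled H; ``walk``: self-avoiding 3.8 A chain
    labelled C. rsa is uniform in [0, 1] in both motifs.
    """
    rng = _rng(seed)
    n = len(protein)
    if motif == "helix":
        coords, ss = _helix_coords(n), ["H"] * n
    elif motif == "walk":
        coords, ss = _walk_coords(n, rng), ["C"] * n
    else:
        raise ValidationError(f"unknown motif {motif!r}")
    rsa = rng.uniform(0.0, 1.0, size=n)
    return protein.attach(ca_coords=coords, ss=ss, rsa=rsa)


def gen_states(length: int, seed) -> tuple[list[str], np.ndarray]:
    """Random ss3/rsa annotation (for corpus sequences)."""
    rng = _rng(seed)
    ss = list(rng.choice(["H", "E", "C"], size=length, p=[0.35, 0.25, 0.40]))
    rsa = rng.uniform(0.0, 1.0, size=length)
    return ss, rsa


def gen_pssm(protein: ProteinRecord, concentration: float = 20.0, seed=0) -> Pssm:
    """Profile with the native residue elevated.

    Weighted percentages per position come from a Dirichlet with the native
    residue's concentration boosted, converted to integers summing exactly to
    100 (largest-remainder rounding). Log-odds are 2*log2(p / background),
    rounded to integers and clipped to [-12, 12].
    """
    if concentration <= 0:
        raise ValidationError("concentration must be > 0")
    rng = _rng(seed)
    bg = np.array([BACKGROUND_FREQUENCIES[a] for a in PSSM_AA_ORDER])
    log_odds, weighted = [], []
    for aa in protein.sequence:
        alpha = np.ones(20)
        alpha[PSSM_AA_ORDER.index(aa)] += concentration
        p = rng.dirichlet(alpha)
        lo = np.clip(np.rint(2.0 * np.log2(np.maximum(p, 1e-4) / bg)), -12, 12)
        pct = np.floor(p * 100).astype(int)
        remainder = 100 - pct.sum()
        order = np.argsort(-(p * 100 - pct))
        pct[order[:remainder]] += 1
        log_odds.append(lo.astype(int))
        weighted.append(pct)
    return Pssm(np.array(log_odds), np.array(weighted, dtype=float))


def mutate_protein(protein: ProteinRecord, n_subs: int, seed, id: str | None = None
                   ) -> ProteinRecord:
    """A near-identical homolog: the protein with n random substitutions."""
    rng = _rng(seed)
    positions = rng.choice(len(protein), size=n_subs, replace=False)
    seq = list(protein.sequence)
    for pos in positions:
        choices = [a for a in PSSM_AA_ORDER if a != seq[pos]]
        seq[pos] = choices[rng.integers(len(choices))]
    out = ProteinRecord(id=id or f"{protein.id}_hom", sequence="".join(seq))
    return out.attach(ca_coords=protein.ca_coords, ss=protein.ss,
                      rsa=protein.rsa, profile=None)


# ---------------------------------------------------------------------------
# Corpora and potential tables
# ---------------------------------------------------------------------------


def gen_corpora(n_seqs: int = 20, length: int = 80, seed=0,
                charged_boost: float = 1.8):
    """Two contrasting sequence corpora with annotations.

    Corpus A is enriched in charged residues (RKHDE boosted by
    ``charged_boost``) relative to the background corpus B, so occurrence
    potentials carry real compositional signal.
    """
    rng = _rng(seed)
    boosted = dict(BACKGROUND_FREQUENCIES)
    for aa in "RKHDE":
        boosted[aa] *= charged_boost
    total = sum(boosted.values())
    boosted = {k: v / total for k, v in boosted.items()}

    corpus_a = [gen_sequence(length, rng, boosted) for _ in range(n_seqs)]
    corpus_b = [gen_sequence(length, rng) for _ in range(n_seqs)]

    def annotate(seqs):
        out = []
        for seq in seqs:
            ss, rsa = gen_states(len(seq), rng)
            out.append(residue_states(
                ProteinRecord(id="c", sequence=seq).attach(ss=ss, rsa=rsa)))
        return out

    return corpus_a, corpus_b, annotate(corpus_a), annotate(corpus_b)


# ---------------------------------------------------------------------------
# Mutation datasets with planted signal
# ---------------------------------------------------------------------------


def gen_mutation_dataset(proteins: dict[str, ProteinRecord], n_records: int,
                         planted: PlantedModel, multiplicity,
                         pipeline: FeaturePipeline, seed=None) -> MutationDataset:
    """Forward mutation records whose ddG follows the planted model.

    ``multiplicity`` is 1, 2 or "mixed" (70% single / 30% double). Ground
    truth (the planted weights) travels with the returned dataset via the
    caller; noise is drawn from the planted model's seed unless ``seed``
    overrides it.
    """
    if multiplicity not in (1, 2, "mixed"):
        raise ValidationError(f"multiplicity must be 1, 2 or 'mixed', got {multiplicity!r}")
    rng = _rng(planted.seed if seed is None else seed)
    ids = sorted(proteins)
    records = []
    dataset = MutationDataset(records=records, proteins=dict(proteins))
    seen = set()
    for i in range(n_records):
        protein = proteins[ids[i % len(ids)]]
        m = multiplicity if multiplicity != "mixed" else (1 if rng.random() < 0.7 else 2)
        for _ in range(500):
            positions = sorted(int(p) + 1 for p in
                               rng.choice(len(protein), size=m, replace=False))
            subs = []
            for pos in positions:
                wt = protein.sequence[pos - 1]
                choices = [a for a in PSSM_AA_ORDER if a != wt]
                subs.append(Substitution(wt, pos, choices[rng.integers(19)]))
            key = (protein.id, tuple(str(s) for s in subs))
            if key not in seen:
                seen.add(key)
                break
        else:
            raise ValidationError("could not draw a fresh mutation; too few positions")
        rec = MutationRecord(protein_id=protein.id, subs=tuple(subs), ddg=0.0)
        features = pipeline.featurize_record(dataset, rec)
        ddg = planted.signal(features) + rng.normal(0.0, planted.noise_sd)
        records.append(MutationRecord(protein_id=protein.id, subs=tuple(subs), ddg=ddg))
    dataset.validate()
    return dataset


@dataclass
class Benchmark:
    """A complete synthetic study: proteins, tables, pipeline, planted truth."""

    dataset: MutationDataset
    pipeline: FeaturePipeline
    planted: PlantedModel
    signal_sd: float
    proteins: dict[str, ProteinRecord] = field(default_factory=dict)


def make_benchmark(seed: int = 0, n_single: int = 500, n_double: int = 200,
                   n_proteins: int = 12, length: int = 120,
                   snr: float = 2.0, target_signal_sd: float = 1.5,
                   mode: str = "sequence",
                   weights: dict[str, float] | None = None) -> Benchmark:
    """Build the standard synthetic study used in tests and evaluation.

    Weights are rescaled so the noise-free ddG signal has a standard
    deviation of ``target_signal_sd`` kcal/mol; Gaussian noise of sd
    ``target_signal_sd / snr`` is then added (default signal:noise 2:1).
    """
    rng = _rng(seed)
    corpus_a, corpus_b, states_a, states_b = gen_corpora(seed=rng)
    tables = build_sequence_tables(corpus_a, corpus_b, states_a, states_b)

    dt_tables = None
    if mode == "structure":
        from .delaunay import build_dt_tables, tessellate
        corp_structs = []
        for name, seqs in (("a", corpus_a), ("b", corpus_b)):
            structs = []
            for j, seq in enumerate(seqs):
                p = gen_structure(ProteinRecord(id=f"{name}{j}", sequence=seq),
                                  motif="walk", seed=rng)
                structs.append((seq, tessellate(p.ca_coords)))
            corp_structs.append(structs)
        dt_tables = build_dt_tables(*corp_structs)

    pipeline = FeaturePipeline(tables=tables, dt_tables=dt_tables, mode=mode)

    proteins = {}
    for i in range(n_proteins):
        p = gen_protein(length, rng, id=f"p{i:02d}")
        p = gen_structure(p, motif="walk" if mode == "structure" else "helix", seed=rng)
        p = p.attach(profile=gen_pssm(p, seed=rng))
        proteins[p.id] = p

    base_weights = dict(weights or DEFAULT_PLANTED_WEIGHTS)
    probe = PlantedModel(weights=base_weights, noise_sd=0.0, seed=int(rng.integers(2**31)))
    noise_free = gen_mutation_dataset(proteins, n_single, probe, 1, pipeline, seed=rng)
    if n_double:
        d2 = gen_mutation_dataset(proteins, n_double, probe, 2, pipeline, seed=rng)
        noise_free.records.extend(d2.records)
    signals = np.array([r.ddg for r in noise_free.records])
    sd = float(np.std(signals))
    if sd == 0:
        raise ValidationError("planted signal is degenerate")
    scale = target_signal_sd / sd
    noise_sd = target_signal_sd / snr

    planted = PlantedModel(weights={k: v * scale for k, v in base_weights.items()},
                           noise_sd=noise_sd, seed=int(rng.integers(2**31)))
    noise_rng = _rng(planted.seed)
    records = [MutationRecord(protein_id=r.protein_id, subs=r.subs,
                              ddg=r.ddg * scale + noise_rng.normal(0.0, noise_sd))
               for r in noise_free.records]
    dataset = MutationDataset(records=records, proteins=dict(proteins))
    dataset.validate()
    return Benchmark(dataset=dataset, pipeline=pipeline, planted=planted,
                     signal_sd=target_signal_sd, proteins=proteins)
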