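"""Synthetic gp8-amplicon sequencing runs with planted tissue-selective motifs.

The generator emulates the data a targeted single-end MiSeq run of a landscape
(p8-type) phage display library produces: 150 bp reads carrying a degenerate
27-nt in-frame insert between fixed gp8 flanking sequences, a mixture of sense
and anti-sense orientations, per-base Phred qualities, and substitution
sequencing errors.  Multiple tissue samples share one background peptide pool;
per-tissue 3-mer motif enrichments are planted on top of it so that every
downstream stage of the pipeline can be exercised against known ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import (
    AMINO_ACIDS,
    CODONS_BY_AA,
    NNK_CODONS_BY_AA,
    STOP_CODONS,
    is_valid_peptide,
    reverse_complement,
    translate,
)

NUCLEOTIDES = "ACGT"


@dataclass(frozen=True)
class LibraryDesign:
    """Fixed sequence context of the gp8 amplicon around the degenerate insert.

    Defaults are the f8/9 landscape-library flanks; anti-sense flanks are
    derived by reverse complement of the sense strings unless literal
    anti-sense strings are supplied (``antisense_override``).
    """

    sense_upstream_flank: str = "ATGCTGTCTTTCGCTGCA"
    sense_downstream_flank: str = "CCCGCAAAAGCGGCCTTTGACTCCCTGCAAGCTAGCGC"
    insert_length_nt: int = 27
    peptide_length: int = 9
    antisense_override: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.insert_length_nt != 3 * self.peptide_length:
            raise ValueError("insert_length_nt must be 3 x peptide_length")
        for flank in (self.sense_upstream_flank, self.sense_downstream_flank):
            if not flank or any(b not in NUCLEOTIDES for b in flank):
                raise ValueError(f"invalid flank sequence: {flank!r}")

    @property
    def antisense_upstream_flank(self) -> str:
        """Flank 5' of the insert on an anti-sense read."""
        if self.antisense_override is not None:
            return self.antisense_override[0]
        return reverse_complement(self.sense_downstream_flank)

    @property
    def antisense_downstream_flank(self) -> str:
        if self.antisense_override is not None:
            return self.antisense_override[1]
        return reverse_complement(self.sense_upstream_flank)

    @property
    def construct_length(self) -> int:
        return (
            len(self.sense_upstream_flank)
            + self.insert_length_nt
            + len(self.sense_downstream_flank)
        )


@dataclass(frozen=True)
class PlantedEnrichment:
    """One ground-truth tissue-selective motif: ``motif`` enriched ``fold``-fold
    over its background frequency in tissue ``tissue_id``."""

    motif: str
    tissue_id: str
    fold: float

    def __post_init__(self) -> None:
        if not is_valid_peptide(self.motif):
            raise ValueError(f"motif must use the 20 standard residues: {self.motif!r}")
        if not self.fold > 0:
            raise ValueError("fold must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    n_tissues: int = 8
    n_reads_per_tissue: int = 10_000
    n_background_peptides: int = 20_000
    sense_fraction: float = 0.5
    read_length: int = 150
    substitution_error_rate: float = 0.001
    quality_mean: float = 36.0
    quality_sd: float = 2.0
    stop_codon_policy: str = "forbid"  # "forbid" | "allow"
    stop_injection_rate: float = 0.02  # used only when stop_codon_policy == "allow"
    codon_policy: str = "uniform"  # "first" | "uniform" | "nnk"
    amino_acid_weights: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sense_fraction <= 1.0:
            raise ValueError("sense_fraction must be in [0, 1]")
        if self.stop_codon_policy not in ("forbid", "allow"):
            raise ValueError("stop_codon_policy must be 'forbid' or 'allow'")
        if not 0.0 <= self.substitution_error_rate < 1.0:
            raise ValueError("substitution_error_rate must be in [0, 1)")

    def validate_against(self, design: LibraryDesign) -> None:
        if self.read_length < design.construct_length:
            raise ValueError(
                f"read_length {self.read_length} shorter than the flanked insert "
                f"({design.construct_length} nt)"
            )

    def tissue_ids(self) -> list[str]:
        return [f"tissue_{i + 1}" for i in range(self.n_tissues)]

    def residue_probabilities(self) -> np.ndarray:
        if self.amino_acid_weights is None:
            return np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
        w = np.array([float(self.amino_acid_weights.get(aa, 0.0)) for aa in AMINO_ACIDS])
        if w.sum() <= 0:
            raise ValueError("amino_acid_weights must have positive total mass")
        return w / w.sum()


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline is asked to recover."""

    peptides: pd.DataFrame  # tissue, peptide, read_count, n_variants
    variants: pd.DataFrame  # tissue, insert, peptide, read_count
    tissue_pools: dict[str, list[str]]  # full unique-peptide pool per tissue
    library_pool: list[str]  # independent unselected-library sample
    enrichments: list[PlantedEnrichment]
    config: SimulationConfig

    def peptide_records(self, tissue_id: str):
        """Recovered-peptide view of one tissue (import deferred: avoids cycle)."""
        from .processing import PeptideRecord

        sub = self.peptides[self.peptides["tissue"] == tissue_id]
        return [
            PeptideRecord(row.peptide, int(row.read_count), int(row.n_variants))
            for row in sub.itertuples()
        ]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "peptides": outdir / "ground_truth_peptides.tsv",
            "variants": outdir / "ground_truth_variants.tsv",
            "manifest": outdir / "simulation_manifest.json",
        }
        self.peptides.to_csv(paths["peptides"], sep="\t", index=False)
        self.variants.to_csv(paths["variants"], sep="\t", index=False)
        manifest = {
            "config": dataclasses.asdict(self.config),
            "enrichments": [dataclasses.asdict(e) for e in self.enrichments],
            "n_tissues": len(self.tissue_pools),
        }
        paths["manifest"].write_text(json.dumps(manifest, indent=2, default=str))
        return paths


def reverse_translate(
    peptide: str,
    codon_policy: str = "uniform",
    rng: np.random.Generator | None = None,
) -> str:
    """Encode a peptide as DNA under the chosen codon-degeneracy policy.

    ``first`` takes the first codon of each residue in classical T/C/A/G
    genetic-code-table order (deterministic); ``uniform`` samples uniformly
    among synonymous codons; ``nnk`` samples among NNK codons only.
    """
    if not is_valid_peptide(peptide):
        bad = sorted(set(peptide) - set(AMINO_ACIDS))
        raise ValueError(f"unknown residue(s) {bad} in peptide {peptide!r}")
    if codon_policy == "first":
        return "".join(CODONS_BY_AA[aa][0] for aa in peptide)
    table = {"uniform": CODONS_BY_AA, "nnk": NNK_CODONS_BY_AA}.get(codon_policy)
    if table is None:
        raise ValueError(f"unknown codon_policy {codon_policy!r}")
    if rng is None:
        raise ValueError("random codon policies require an rng")
    return "".join(table[aa][rng.integers(len(table[aa]))] for aa in peptide)


def motif_containment_probability(
    motif: str, length: int, residue_probs: np.ndarray | None = None
) -> float:
    """P(an i.i.d. random peptide of ``length`` contains ``motif`` as substring).

    Exact, via the KMP failure automaton of the motif (handles self-overlap,
    e.g. "AAA").
    """
    m = len(motif)
    if residue_probs is None:
        residue_probs = np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    probs = {aa: residue_probs[i] for i, aa in enumerate(AMINO_ACIDS)}

    def next_state(state: int, ch: str) -> int:
        s = motif[:state] + ch
        for k in range(min(len(s), m), -1, -1):
            if s.endswith(motif[:k]):
                return k
        return 0

    # state m is absorbing
    dist = np.zeros(m + 1)
    dist[0] = 1.0
    for _ in range(length):
        new = np.zeros(m + 1)
        new[m] = dist[m]
        for state in range(m):
            if dist[state] == 0:
                continue
            for aa, p in probs.items():
                new[next_state(state, aa)] += dist[state] * p
        dist = new
    return float(dist[m])


def _random_peptides(
    n: int, length: int, rng: np.random.Generator, residue_probs: np.ndarray
) -> list[str]:
    aas = np.array(list(AMINO_ACIDS))
    mat = rng.choice(aas, size=(n, length), p=residue_probs)
    return ["".join(row) for row in mat]


def _unique_random_peptides(
    n: int, length: int, rng: np.random.Generator, residue_probs: np.ndarray
) -> list[str]:
    seen: dict[str, None] = {}
    while len(seen) < n:
        for p in _random_peptides(n - len(seen), length, rng, residue_probs):
            if p not in seen:
                seen[p] = None
    return list(seen)


def generate_peptide_pool(
    config: SimulationConfig,
    enrichments: Sequence[PlantedEnrichment] = (),
    peptide_length: int = 9,
) -> GroundTruth:
    """Draw the shared background pool, plant per-tissue motif enrichments, and
    assign ground-truth read counts.

    Planting targets the analytic expected motif frequency: enough extra
    motif-bearing peptides are injected into a tissue's pool that the expected
    unique-peptide count of the motif reaches ``fold`` x its expectation under
    the background residue composition.  ``fold == 1`` plants nothing.
    """
    seen_pairs = set()
    for e in enrichments:
        key = (e.tissue_id, e.motif)
        if key in seen_pairs:
            raise ValueError(f"duplicate planted motif {e.motif!r} for {e.tissue_id!r}")
        seen_pairs.add(key)

    rng = np.random.default_rng(config.seed)
    residue_probs = config.residue_probabilities()
    length = peptide_length
    background = _unique_random_peptides(
        config.n_background_peptides, length, rng, residue_probs
    )
    library_pool = _unique_random_peptides(
        max(config.n_background_peptides, 1), length, rng, residue_probs
    )

    tissue_ids = config.tissue_ids()
    known = set(tissue_ids)
    for e in enrichments:
        if e.tissue_id not in known:
            raise ValueError(f"planted tissue {e.tissue_id!r} not in the simulated set")

    tissue_pools: dict[str, list[str]] = {}
    for tissue in tissue_ids:
        pool = list(background)
        pool_set = set(pool)
        for e in enrichments:
            if e.tissue_id != tissue or e.fold == 1.0:
                continue
            if e.fold < 1.0:
                raise ValueError(
                    f"fold {e.fold} < 1 is unreachable by injecting peptides"
                )
            n_bg = len(background)
            if n_bg == 0:
                expected = 0.0
            else:
                expected = n_bg * motif_containment_probability(
                    e.motif, length, residue_probs
                )
            realized = sum(1 for p in background if e.motif in p)
            if n_bg == 0 and e.fold != 1.0:
                # degenerate pool: plant a single motif-bearing peptide
                target = 1.0
            else:
                target = e.fold * expected
            k = int(round(target)) - realized
            if k < 0:
                k = 0
            if n_bg == 0 and k == 0:
                k = 1
            injected = 0
            while injected < k:
                p = _random_peptides(1, length, rng, residue_probs)[0]
                start = int(rng.integers(0, length - len(e.motif) + 1))
                p = p[:start] + e.motif + p[start + len(e.motif):]
                if p not in pool_set:
                    pool.append(p)
                    pool_set.add(p)
                    injected += 1
        tissue_pools[tissue] = pool

    codon_rng = np.random.default_rng([config.seed, 1])
    pep_rows: list[tuple] = []
    var_rows: list[tuple] = []
    for tissue in tissue_ids:
        pool = tissue_pools[tissue]
        counts = rng.multinomial(
            config.n_reads_per_tissue, np.full(len(pool), 1.0 / len(pool))
        )
        for peptide, count in zip(pool, counts):
            if count == 0:
                continue
            encodings = Counter(
                reverse_translate(peptide, config.codon_policy, codon_rng)
                for _ in range(count)
            )
            pep_rows.append((tissue, peptide, int(count), len(encodings)))
            for insert, n in sorted(encodings.items()):
                var_rows.append((tissue, insert, peptide, int(n)))

    peptides = pd.DataFrame(
        pep_rows, columns=["tissue", "peptide", "read_count", "n_variants"]
    )
    variants = pd.DataFrame(
        var_rows, columns=["tissue", "insert", "peptide", "read_count"]
    )
    return GroundTruth(
        peptides=peptides,
        variants=variants,
        tissue_pools=tissue_pools,
        library_pool=library_pool,
        enrichments=list(enrichments),
        config=config,
    )


def _apply_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode("ascii")


def iter_reads(
    truth: GroundTruth,
    design: LibraryDesign,
    config: SimulationConfig,
    tissue_id: str,
) -> Iterator[tuple[str, str, list[int]]]:
    """Yield ``(read_id, sequence, phred_qualities)`` for one tissue sample.

    Deterministic given ``config.seed`` and the tissue's position in the
    simulated set.
    """
    config.validate_against(design)
    t_index = config.tissue_ids().index(tissue_id)
    rng = np.random.default_rng([config.seed, 2, t_index])
    sub = truth.variants[truth.variants["tissue"] == tissue_id]
    nt = np.array(list(NUCLEOTIDES))
    i = 0
    for row in sub.itertuples():
        for _ in range(int(row.read_count)):
            insert = row.insert
            if (
                config.stop_codon_policy == "allow"
                and rng.random() < config.stop_injection_rate
            ):
                codon_i = int(rng.integers(len(insert) // 3)) * 3
                stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
                insert = insert[:codon_i] + stop + insert[codon_i + 3:]
            construct = (
                design.sense_upstream_flank + insert + design.sense_downstream_flank
            )
            sense = rng.random() < config.sense_fraction
            seq = construct if sense else reverse_complement(construct)
            pad_len = config.read_length - len(seq)
            if pad_len > 0:
                seq += "".join(rng.choice(nt, size=pad_len))
            seq = _apply_substitutions(seq, config.substitution_error_rate, rng)
            quals = np.clip(
                np.rint(rng.normal(config.quality_mean, config.quality_sd, len(seq))),
                2,
                40,
            ).astype(int)
            strand = "sense" if sense else "antisense"
            yield f"{tissue_id}:{i}:{strand}", seq, quals.tolist()
            i += 1


def synthesize_reads(
    truth: GroundTruth,
    design: LibraryDesign,
    config: SimulationConfig,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write one Phred+33 FASTQ per tissue plus ground-truth TSVs and a run
    manifest; returns the tissue -> FASTQ path mapping."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fastq_paths: dict[str, Path] = {}
    for tissue in config.tissue_ids():
        path = outdir / f"{tissue}.fastq"
        records = (
            SeqRecord(
                Seq(seq),
                id=read_id,
                description="",
                letter_annotations={"phred_quality": quals},
            )
            for read_id, seq, quals in iter_reads(truth, design, config, tissue)
        )
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fastq")
        fastq_paths[tissue] = path
    truth.write(outdir)
    return fastq_paths
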