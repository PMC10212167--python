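"""Seeded mutation simulator with exact ground truth.

Generates reference panels, mutated patient-style samples (long sequences
carrying SNVs, insertions and deletions at known positions) and short reads
sliced from those samples, standing in for curated somatic-mutation
databases and hospital sequencing data. Every dataset is reproducible from
its config + seed, and every mutated base is tracked so that per-position
truth labels can be built exactly.

Default mutation-type proportions follow the breast-cancer somatic spectrum
used throughout the package: 76.33% SNV, 10.79% insertion, 12.88% deletion
(duplications folded into insertions). Short reads are capped at 144 bp.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import numpy as np

from .encoding import (LabelSequence, NucleotideSequence, make_label_sequence,
                       read_fasta, read_labels_tsv, write_fasta,
                       write_labels_tsv)
from .errors import (ConfigError, InvalidArgumentError,
                     SimulationInfeasibleError)

_BASES = np.array(list("ACGT"))

#: Default SNV / insertion / deletion proportions.
DEFAULT_TYPE_PROPS = (0.7633, 0.1079, 0.1288)

#: Maximum short-read length.
MAX_READ_LEN = 144


@dataclass
class MutationRecord:
    """One ground-truth mutation event, positioned on the mutated sample.

    ``position`` is a 0-based index into the *sample* sequence: for an SNV
    the substituted base, for an insertion the first inserted base, for a
    deletion the base immediately 3' of the removed span.
    """

    sample_id: str
    ref_id: str
    position: int
    type: str                 # one of SNV, INS, DEL
    ref_allele: str           # empty for INS
    alt_allele: str           # empty for DEL
    length: int

    def __post_init__(self):
        if self.type == "SNV":
            ok = len(self.ref_allele) == 1 and len(self.alt_allele) == 1 \
                and self.ref_allele != self.alt_allele
        elif self.type == "INS":
            ok = len(self.alt_allele) == self.length >= 1 and self.ref_allele == ""
        elif self.type == "DEL":
            ok = len(self.ref_allele) == self.length >= 1 and self.alt_allele == ""
        else:
            ok = False
        if not ok:
            raise InvalidArgumentError(f"inconsistent mutation record: {self}")


@dataclass
class SimulatorConfig:
    n_refs: int = 4
    ref_len: int = 300
    n_samples: int = 100
    muts_per_sample: float = 3.0          # Poisson mean, truncated at >= 1
    fixed_muts: int | None = None         # exact count per sample, overrides the draw
    type_props: tuple = DEFAULT_TYPE_PROPS
    indel_len_range: tuple = (1, 3)       # inclusive
    read_len: int = 100
    reads_per_sample: int = 100
    snv_only_reads: bool = False
    seed: int = 0

    def validate(self) -> "SimulatorConfig":
        if min(self.n_refs, self.ref_len, self.n_samples,
               self.read_len, self.reads_per_sample) < 1:
            raise ConfigError("all simulator counts must be positive")
        if abs(sum(self.type_props) - 1.0) > 1e-9:
            raise ConfigError(f"type_props must sum to 1, got {self.type_props}")
        if self.read_len > MAX_READ_LEN:
            raise ConfigError(f"read_len must be <= {MAX_READ_LEN}")
        lo, hi = self.indel_len_range
        if not (1 <= lo <= hi):
            raise ConfigError("indel_len_range must be 1 <= lo <= hi")
        return self


def generate_references(cfg: SimulatorConfig, rng: np.random.Generator | None = None):
    """Draw n_refs i.i.d.-uniform ACGT sequences of exactly ref_len bases."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    refs = []
    for i in range(cfg.n_refs):
        bases = "".join(_BASES[rng.integers(0, 4, size=cfg.ref_len)])
        refs.append(NucleotideSequence(id=f"ref_{i}", bases=bases))
    return refs


def _draw_mutation_plan(ref_len: int, cfg: SimulatorConfig, rng: np.random.Generator):
    """Choose non-overlapping (ref_start, type, length) triples.

    Reference footprints: SNV and INS occupy one anchor base, DEL occupies
    its deleted span plus the following base (which receives the label), so
    a deletion can never sit flush against the 3' end.
    """
    if cfg.fixed_muts is not None:
        n_mut = cfg.fixed_muts
    else:
        n_mut = 0
        while n_mut < 1:
            n_mut = int(rng.poisson(cfg.muts_per_sample))
    types = rng.choice(["SNV", "INS", "DEL"], size=n_mut, p=list(cfg.type_props))
    lo, hi = cfg.indel_len_range
    plan, taken = [], np.zeros(ref_len, dtype=bool)
    for t in types:
        length = int(rng.integers(lo, hi + 1)) if t in ("INS", "DEL") else 1
        span = length + 1 if t == "DEL" else 1
        placed = False
        for _ in range(200):
            start = int(rng.integers(0, ref_len - span + 1))
            if not taken[start : start + span].any():
                taken[start : start + span] = True
                plan.append((start, t, length))
                placed = True
                break
        if not placed:
            raise SimulationInfeasibleError(
                f"could not place {n_mut} non-overlapping mutations in {ref_len} bp"
            )
    plan.sort(key=lambda p: p[0])
    return plan


def implant_mutations(ref: NucleotideSequence, cfg: SimulatorConfig,
                      rng: np.random.Generator, sample_id: str = "sample_0"):
    """Apply a drawn mutation plan to one reference.

    Returns the mutated sample, its MutationRecords (positions on sample
    coordinates) and the per-position truth LabelSequence. Sample length =
    ref length + inserted - deleted bases.
    """
    max_indel = cfg.indel_len_range[1]
    if len(ref) <= 2 * max_indel:
        raise InvalidArgumentError("reference too short for configured indels")
    plan = _draw_mutation_plan(len(ref), cfg, rng)
    pieces, records = [], []
    cursor = 0          # consumed ref bases
    out_len = 0         # emitted sample bases
    for start, t, length in plan:
        pieces.append(ref.bases[cursor:start])
        out_len += start - cursor
        cursor = start
        if t == "SNV":
            old = ref.bases[start]
            new = str(rng.choice([b for b in "ACGT" if b != old]))
            pieces.append(new)
            records.append(MutationRecord(sample_id, ref.id, out_len, "SNV",
                                          old, new, 1))
            cursor += 1
            out_len += 1
        elif t == "INS":
            ins = "".join(_BASES[rng.integers(0, 4, size=length)])
            pieces.append(ins)
            records.append(MutationRecord(sample_id, ref.id, out_len, "INS",
                                          "", ins, length))
            out_len += length
        else:  # DEL: drop `length` ref bases; label lands on the next base
            deleted = ref.bases[start : start + length]
            records.append(MutationRecord(sample_id, ref.id, out_len, "DEL",
                                          deleted, "", length))
            cursor += length
    pieces.append(ref.bases[cursor:])
    out_len += len(ref) - cursor
    sample = NucleotideSequence(id=sample_id, bases="".join(pieces))
    truth = make_label_sequence(len(sample), records)
    truth = LabelSequence(source_id=sample_id, labels=truth.labels)
    return sample, records, truth


def simulate_reads(sample: NucleotideSequence, truth: LabelSequence,
                   cfg: SimulatorConfig, rng: np.random.Generator):
    """Slice reads_per_sample random substrings of read_len with their labels.

    With ``snv_only_reads`` on, reads whose label slice contains insertion
    or deletion labels are dropped (mirroring an annotation pipeline that
    keeps only normal and SNV-bearing short sequences).
    """
    if cfg.read_len > len(sample):
        raise InvalidArgumentError(
            f"read_len {cfg.read_len} exceeds sample length {len(sample)}"
        )
    starts = rng.integers(0, len(sample) - cfg.read_len + 1,
                          size=cfg.reads_per_sample)
    reads = []
    for j, o in enumerate(map(int, starts)):
        lab = truth.labels[o : o + cfg.read_len]
        if cfg.snv_only_reads and np.isin(lab, (2, 3)).any():
            continue
        rid = f"{sample.id}_read_{j}"
        reads.append((NucleotideSequence(id=rid, bases=sample.bases[o : o + cfg.read_len]),
                      LabelSequence(source_id=rid, labels=lab.copy())))
    return reads


def planned_read_count(cfg: SimulatorConfig) -> int:
    """Total read records a full assembly would produce, without materializing
    any sequence: n_samples x reads_per_sample."""
    cfg.validate()
    return cfg.n_samples * cfg.reads_per_sample


def simulate_dataset(cfg: SimulatorConfig):
    """Full pipeline: references -> mutated samples (+records, +truth).

    Samples cycle round-robin over the reference panel. All randomness
    flows from cfg.seed through one Generator.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    refs = generate_references(cfg, rng)
    samples, records, truths = [], [], []
    for i in range(cfg.n_samples):
        ref = refs[i % cfg.n_refs]
        s, r, t = implant_mutations(ref, cfg, rng, sample_id=f"sample_{i}")
        samples.append(s)
        records.extend(r)
        truths.append(t)
    return refs, samples, records, truths


# ---------------------------------------------------------------------------
# Dataset export / import (FASTA + TSV + manifest, all plain text)
# ---------------------------------------------------------------------------

def export_dataset(samples, records, truths, directory, cfg: SimulatorConfig | None = None):
    """Write samples.fasta, labels.tsv, mutations.tsv and manifest.txt.

    mutations.tsv uses 1-based positions; re-loading with load_dataset
    reproduces the in-memory objects exactly.
    """
    os.makedirs(directory, exist_ok=True)
    write_fasta(samples, os.path.join(directory, "samples.fasta"))
    write_labels_tsv(truths, os.path.join(directory, "labels.tsv"))
    with open(os.path.join(directory, "mutations.tsv"), "w") as fh:
        fh.write("sample_id\tref_id\tposition_1based\ttype\tref_allele\talt_allele\tlength\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.ref_id}\t{r.position + 1}\t{r.type}\t"
                     f"{r.ref_allele}\t{r.alt_allele}\t{r.length}\n")
    with open(os.path.join(directory, "manifest.txt"), "w") as fh:
        fh.write("format=tcncall-dataset-v1\n")
        if cfg is not None:
            for f in dataclasses.fields(cfg):
                v = getattr(cfg, f.name)
                if isinstance(v, tuple):
                    v = ",".join(map(str, v))
                fh.write(f"{f.name}={v}\n")


def load_dataset(directory):
    """Inverse of export_dataset. Returns (samples, records, truths)."""
    samples = read_fasta(os.path.join(directory, "samples.fasta"))
    truths = read_labels_tsv(os.path.join(directory, "labels.tsv"))
    records = []
    with open(os.path.join(directory, "mutations.tsv")) as fh:
        header = fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            sid, rid, pos1, typ, ra, aa, ln = parts
            records.append(MutationRecord(sid, rid, int(pos1) - 1, typ, ra, aa, int(ln)))
    return samples, records, truths
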