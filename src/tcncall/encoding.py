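"""DNA sequence encoding for per-nucleotide sequence labeling.

Converts DNA strings over {A,C,G,T,N} into integer code sequences using
k-mer mapping tables (k = 1, 2 or 3), pads sequences with 'N', reshapes
long sequences into fixed-length overlapping windows, expands codes into
one-hot matrices, and builds per-position class label vectors
(0 = normal, 1 = SNV, 2 = insertion, 3 = deletion) from ground-truth
mutation records.

Coordinate conventions: 0-based half-open internally; 1-based inclusive in
TSV files written for or read by users.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import InvalidArgumentError, InvalidRecordError

logger = logging.getLogger(__name__)

#: Digit order used by the positional base-4 code for k >= 2.
_DIGITS = {"A": 0, "T": 1, "G": 2, "C": 3}

#: The integer (1-mer) mapping. It does NOT follow the k>=2 digit order;
#: it is the mapping T=1, C=2, A=3, G=4 stated for single nucleotides.
_K1_CODES = {"T": 1, "C": 2, "A": 3, "G": 4}

#: Reserved code for any k-window containing a non-ACGT character.
PAD_CODE = 0

#: Label semantics, fixed across the package.
LABEL_NORMAL, LABEL_SNV, LABEL_INS, LABEL_DEL = 0, 1, 2, 3

_VALID_CHARS = set("ACGTN")


@dataclass(frozen=True)
class NucleotideSequence:
    """An identified DNA string over the alphabet {A,C,G,T,N}.

    Bases are uppercased on construction; characters outside the alphabet
    are coerced to 'N' with a logged warning rather than rejected, since
    real FASTA files occasionally carry IUPAC ambiguity codes.
    """

    id: str
    bases: str

    def __post_init__(self):
        if not self.id:
            raise InvalidArgumentError("sequence id must be non-empty")
        up = self.bases.upper()
        if not set(up) <= _VALID_CHARS:
            bad = sorted(set(up) - _VALID_CHARS)
            logger.warning(
                "sequence %s: characters %s outside {A,C,G,T,N} coerced to N",
                self.id, bad,
            )
            up = "".join(c if c in _VALID_CHARS else "N" for c in up)
        object.__setattr__(self, "bases", up)

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class KmerTable:
    """Mapping from k-mers over ACGT to integer codes 1..m, with pad code 0."""

    k: int
    codes: dict[str, int]
    m: int
    pad_code: int = PAD_CODE


@dataclass(frozen=True)
class EncodedSequence:
    """Integer code vector aligned position-by-position to a source sequence.

    ``codes[i]`` encodes the k-mer anchored at base i (stride 1, one code
    per nucleotide), so label vectors stay aligned with the input. Windows
    that contain 'N' or overhang the 3' end carry the pad code 0.
    """

    source_id: str
    codes: np.ndarray
    k: int

    @property
    def n(self) -> int:
        return int(self.codes.shape[0])


@dataclass(frozen=True)
class LabelSequence:
    """Per-position class labels in {0,1,2,3} aligned to a sequence."""

    source_id: str
    labels: np.ndarray

    @property
    def n(self) -> int:
        return int(self.labels.shape[0])


@dataclass
class WindowSet:
    """Fixed-length windows cut identically from codes and labels.

    ``items`` holds (codes, labels, source_id, offset) tuples whose code and
    label vectors all have length exactly ``window_len``; short tails are
    right-padded with code 0 / label 0.
    """

    window_len: int
    overlap: int
    items: list[tuple[np.ndarray, np.ndarray, str, int]] = field(default_factory=list)

    @property
    def stride(self) -> int:
        return self.window_len - self.overlap

    def __len__(self) -> int:
        return len(self.items)


def build_kmer_table(k: int) -> KmerTable:
    """Build the k-mer -> integer code table.

    For k >= 2 the code is positional base 4 with digit order A=0, T=1,
    G=2, C=3: code(s) = 1 + sum_j digit(s[j]) * 4**(k-1-j), so 'AA..A' = 1
    and 'CC..C' = 4**k. For k = 1 the conventional integer mapping
    T=1, C=2, A=3, G=4 is used instead (it predates the k-mer tables and
    does not follow their digit order).
    """
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise InvalidArgumentError(f"k must be a positive integer, got {k!r}")
    if k == 1:
        return KmerTable(k=1, codes=dict(_K1_CODES), m=4)
    codes: dict[str, int] = {}
    alphabet = sorted(_DIGITS, key=_DIGITS.get)

    def rec(prefix: str):
        if len(prefix) == k:
            c = 1 + sum(_DIGITS[ch] * 4 ** (k - 1 - j) for j, ch in enumerate(prefix))
            codes[prefix] = c
            return
        for ch in alphabet:
            rec(prefix + ch)

    rec("")
    return KmerTable(k=k, codes=codes, m=4 ** k)


def _digit_array(bases: str, table: KmerTable) -> np.ndarray:
    """Per-base digit for the positional code; -1 marks non-ACGT."""
    lut = np.full(256, -1, dtype=np.int64)
    if table.k == 1:
        for ch, code in _K1_CODES.items():
            lut[ord(ch)] = code  # direct codes for the 1-mer special case
    else:
        for ch, d in _DIGITS.items():
            lut[ord(ch)] = d
    raw = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    return lut[raw]


def encode_sequence(seq: NucleotideSequence, table: KmerTable) -> EncodedSequence:
    """Encode a sequence at stride 1: one code per nucleotide position.

    Position i carries the code of bases[i : i+k]. Any window containing a
    non-ACGT character, or overhanging the sequence end, yields code 0 so
    that the output length always equals the input length and labels stay
    aligned.
    """
    if len(seq) == 0:
        raise InvalidArgumentError("cannot encode an empty sequence")
    n, k = len(seq), table.k
    d = _digit_array(seq.bases, table)
    codes = np.zeros(n, dtype=np.int64)
    if k == 1:
        valid = d >= 0
        codes[valid] = d[valid]
        return EncodedSequence(source_id=seq.id, codes=codes, k=1)
    if n >= k:
        m_pos = n - k + 1
        acc = np.zeros(m_pos, dtype=np.int64)
        ok = np.ones(m_pos, dtype=bool)
        for j in range(k):
            dj = d[j : j + m_pos]
            ok &= dj >= 0
            acc = acc * 4 + np.where(dj >= 0, dj, 0)
        codes[:m_pos] = np.where(ok, acc + 1, 0)
    return EncodedSequence(source_id=seq.id, codes=codes, k=k)


def pad_to_length(seq: NucleotideSequence, length: int) -> NucleotideSequence:
    """Right-pad a sequence with 'N' up to ``length``."""
    if len(seq) > length:
        raise InvalidArgumentError(
            f"sequence {seq.id} (length {len(seq)}) exceeds target length {length}"
        )
    return NucleotideSequence(id=seq.id, bases=seq.bases + "N" * (length - len(seq)))


def make_label_sequence(sample_length: int, records) -> LabelSequence:
    """Build the per-position label vector for one sample from its records.

    Conventions: an SNV labels the substituted position 1; an insertion
    labels every inserted position 2; a deletion labels the single sample
    position immediately 3' of the deleted span 3 (the deleted bases are
    absent from the sample, so a proxy position is required). When two
    records touch one position, deletion > insertion > SNV wins.
    """
    labels = np.zeros(sample_length, dtype=np.int64)
    # ascending precedence: later writes win, so order SNV, INS, DEL
    for wanted, label in (("SNV", LABEL_SNV), ("INS", LABEL_INS), ("DEL", LABEL_DEL)):
        for rec in records:
            if rec.type != wanted:
                continue
            span = rec.length if rec.type == "INS" else 1
            if rec.position < 0 or rec.position + span > sample_length:
                raise InvalidRecordError(
                    f"record {rec} out of range for sample of length {sample_length}"
                )
            labels[rec.position : rec.position + span] = label
    sid = records[0].sample_id if records else ""
    return LabelSequence(source_id=sid, labels=labels)


def window_reshape(codes: EncodedSequence, labels: LabelSequence,
                   window_len: int = 150, overlap: int = 50) -> WindowSet:
    """Cut aligned codes and labels into fixed-length overlapping windows.

    Windows start at offsets 0, S, 2S, ... with stride S = window_len -
    overlap; a new window is added while the previous one did not reach the
    sequence end, so a length-n input yields ceil((n - W) / S) + 1 windows
    (minimum 1). The final window is right-padded with code 0 / label 0.
    """
    if overlap < 0 or overlap >= window_len:
        raise InvalidArgumentError(
            f"overlap must satisfy 0 <= O < W, got O={overlap}, W={window_len}"
        )
    if codes.n != labels.n:
        raise InvalidArgumentError(
            f"codes (n={codes.n}) and labels (n={labels.n}) differ in length"
        )
    n, W = codes.n, window_len
    S = W - overlap
    ws = WindowSet(window_len=W, overlap=overlap)
    offset = 0
    while True:
        c = codes.codes[offset : offset + W]
        l = labels.labels[offset : offset + W]
        if c.shape[0] < W:
            c = np.pad(c, (0, W - c.shape[0]))
            l = np.pad(l, (0, W - l.shape[0]))
        ws.items.append((c, l, codes.source_id, offset))
        if offset + W >= n:
            break
        offset += S
    return ws


def one_hot_encode(codes, m: int) -> np.ndarray:
    """Expand a code vector into an (m+1) x n binary matrix.

    Row 0 is the padding channel; column t is the unit vector for codes[t].
    """
    arr = codes.codes if isinstance(codes, EncodedSequence) else np.asarray(codes)
    if arr.size and (arr.max() > m or arr.min() < 0):
        raise InvalidArgumentError(f"codes must lie in 0..{m}")
    out = np.zeros((m + 1, arr.shape[0]), dtype=np.float32)
    out[arr, np.arange(arr.shape[0])] = 1.0
    return out


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[NucleotideSequence]:
    """Load sequences from FASTA (wrapped or single-line), uppercasing bases."""
    return [NucleotideSequence(id=rec.id, bases=str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.bases), width):
                fh.write(s.bases[i : i + width] + "\n")
            if len(s.bases) == 0:
                fh.write("\n")


def write_labels_tsv(labels, path) -> None:
    """One row per sequence: sequence_id TAB comma-separated labels."""
    with open(path, "w") as fh:
        fh.write("sequence_id\tlabels\n")
        for lab in labels:
            fh.write(f"{lab.source_id}\t{','.join(map(str, lab.labels.tolist()))}\n")


def read_labels_tsv(path) -> list[LabelSequence]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        vec = np.array([int(x) for x in row["labels"].split(",")], dtype=np.int64) \
            if isinstance(row["labels"], str) and row["labels"] else np.zeros(0, dtype=np.int64)
        out.append(LabelSequence(source_id=row["sequence_id"], labels=vec))
    return out


def write_encoded_matrix(mat: np.ndarray, path) -> None:
    """Dense whitespace-delimited dump of an encoded/one-hot matrix (debugging)."""
    np.savetxt(path, mat, fmt="%g")
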