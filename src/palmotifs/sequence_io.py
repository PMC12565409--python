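"""Sequence and motif file IO plus coordinate-aware upstream extraction.

Handles FASTA (via Biopython), the MEME minimal motif text format
("MEME version 4" dialect, the lingua franca of motif toolchains), a
5-column feature TSV (contig, start, end, strand, gene_id; 0-based
half-open), a thin GFF3 adapter for CDS features, strand-aware
extraction of fixed-length upstream promoter regions, and the
conserved-site mutant-probe design rule used for binding assays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matrix import (
    BASES,
    FrequencyMatrix,
    MotifRecord,
    information_content,
)

logger = logging.getLogger(__name__)

DEFAULT_UPSTREAM_LENGTH = 200

_TRANSITION = {"G": "A", "A": "G", "C": "T", "T": "C"}


class MemeParseError(ValueError):
    """Malformed MEME minimal motif file; message names the offending line."""


@dataclass(frozen=True)
class FeatureRecord:
    """A gene/CDS location: contig, 0-based half-open span, strand, id."""

    contig: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad span [{self.start}, {self.end}) for {self.gene_id}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class UpstreamRecord:
    """One upstream region with full provenance.

    ``sequence`` reads 5'->3' on the gene's coding strand; ``start``/
    ``end`` are forward-strand genome coordinates (0-based half-open).
    ``truncated`` flags regions shortened by a contig edge.
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    sequence: str
    truncated: bool = False


@dataclass
class UpstreamSet:
    """A provenance-tagged collection of upstream sequences.

    Iterating yields ``UpstreamRecord``s; ``name`` tags the source
    homolog family so pooled downstream tables stay traceable.
    """

    records: list[UpstreamRecord] = field(default_factory=list)
    name: str = ""

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i) -> UpstreamRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    @classmethod
    def from_sequences(cls, named_seqs, name: str = "") -> "UpstreamSet":
        """Build from (id, sequence) pairs with placeholder coordinates."""
        recs = [
            UpstreamRecord(gene_id=gid, contig="", start=0, end=len(seq),
                           strand="+", sequence=str(seq).upper())
            for gid, seq in named_seqs
        ]
        return cls(records=recs, name=name)

    @classmethod
    def from_fasta(cls, path, name: str = "") -> "UpstreamSet":
        pairs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        return cls.from_sequences(pairs, name=name or str(path))

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(r.sequence), id=r.gene_id, description="")
            for r in self.records
        ]
        SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# upstream extraction
# ---------------------------------------------------------------------------

def extract_upstream(
    genome: dict[str, str],
    features: list[FeatureRecord],
    length: int = DEFAULT_UPSTREAM_LENGTH,
    name: str = "",
) -> UpstreamSet:
    """Fixed-length regions immediately 5' of each feature's reading frame.

    A '+'-strand gene at [s, e) yields [max(0, s - length), s) read
    forward; a '-'-strand gene yields [e, min(L, e + length)) reverse-
    complemented, so every returned sequence reads toward the start
    codon on the coding strand.  Regions truncated by a contig edge are
    kept and flagged; zero-length regions are skipped with a warning.
    """
    records: list[UpstreamRecord] = []
    for feat in features:
        if feat.contig not in genome:
            raise KeyError(
                f"feature {feat.gene_id}: contig {feat.contig!r} not in genome"
            )
        contig_seq = genome[feat.contig]
        clen = len(contig_seq)
        if feat.end > clen:
            raise ValueError(
                f"feature {feat.gene_id} extends past contig end ({feat.end} > {clen})"
            )
        if feat.strand == "+":
            start, end = max(0, feat.start - length), feat.start
            seq = contig_seq[start:end]
        else:
            start, end = feat.end, min(clen, feat.end + length)
            seq = str(Seq(contig_seq[start:end]).reverse_complement())
        if end - start == 0:
            logger.warning("feature %s: zero-length upstream region skipped", feat.gene_id)
            continue
        records.append(
            UpstreamRecord(
                gene_id=feat.gene_id, contig=feat.contig, start=start, end=end,
                strand=feat.strand, sequence=seq.upper(),
                truncated=(end - start) < length,
            )
        )
    return UpstreamSet(records=records, name=name)


def read_feature_tsv(path) -> list[FeatureRecord]:
    """5-column feature table: contig, start, end, strand, gene_id.

    Coordinates 0-based half-open; lines starting with '#' are ignored.
    """
    feats: list[FeatureRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 tab-separated columns")
            contig, start, end, strand, gene_id = parts
            feats.append(FeatureRecord(contig, int(start), int(end), strand, gene_id))
    return feats


def read_gff3_cds(path) -> list[FeatureRecord]:
    """CDS features from a GFF3 file, converted to 0-based half-open."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    feats = []
    for cds in db.features_of_type("CDS", order_by=("seqid", "start")):
        gene_id = (
            cds.attributes.get("ID", [None])[0]
            or cds.attributes.get("Parent", [None])[0]
            or f"{cds.seqid}:{cds.start}-{cds.end}"
        )
        feats.append(
            FeatureRecord(
                contig=cds.seqid, start=cds.start - 1, end=cds.end,
                strand=cds.strand, gene_id=gene_id,
            )
        )
    return feats


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def write_meme_minimal(motifs: list[MotifRecord], path) -> None:
    """Write motifs in the MEME minimal ("MEME version 4") text dialect."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write("ALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= {m.nsites} E= 0\n"
            )
            for j in range(m.width):
                fh.write(" ".join(f"{m.matrix.probs[b, j]:.6f}" for b in range(4)) + "\n")
            fh.write("\n")


def read_meme_minimal(path) -> list[MotifRecord]:
    """Parse a MEME minimal motif file into MotifRecords.

    Validates the version line, alphabet, declared width vs. row count,
    and column normalisation; errors name the offending line.
    """
    with open(path) as fh:
        lines = fh.readlines()

    def err(lineno: int, msg: str):
        raise MemeParseError(f"{path}:{lineno}: {msg}")

    if not any(line.strip().lower().startswith("meme version") for line in lines[:5]):
        err(1, "missing 'MEME version' header line")
    alphabet_ok = False
    for line in lines:
        s = line.strip()
        if s.upper().startswith("ALPHABET"):
            letters = s.split("=", 1)[-1].replace(" ", "")
            if set(letters.upper()) != set(BASES):
                err(lines.index(line) + 1, f"unsupported alphabet {letters!r}")
            alphabet_ok = True
            break
    if not alphabet_ok:
        err(1, "missing ALPHABET line")

    motifs: list[MotifRecord] = []
    i = 0
    while i < len(lines):
        s = lines[i].strip()
        if not s.startswith("MOTIF"):
            i += 1
            continue
        parts = s.split()
        if len(parts) < 2:
            err(i + 1, "MOTIF line without an identifier")
        motif_id = parts[1]
        i += 1
        while i < len(lines) and not lines[i].strip().startswith("letter-probability matrix"):
            if lines[i].strip().startswith("MOTIF"):
                err(i + 1, f"motif {motif_id}: no letter-probability matrix found")
            i += 1
        if i >= len(lines):
            err(len(lines), f"motif {motif_id}: no letter-probability matrix found")
        header = lines[i].strip()
        tokens = header.split()
        width = nsites = None
        for t, nxt in zip(tokens, tokens[1:] + [""]):
            if t == "w=":
                width = int(nxt)
            elif t == "nsites=":
                nsites = int(nxt)
        if width is None:
            err(i + 1, f"motif {motif_id}: matrix header lacks 'w='")
        if nsites is None:
            nsites = 20
        matrix_line = i + 1
        rows = []
        i += 1
        while i < len(lines):
            s = lines[i].strip()
            if not s or s.startswith(("MOTIF", "URL", "letter-probability")):
                break
            vals = s.split()
            if len(vals) != 4:
                err(i + 1, f"motif {motif_id}: expected 4 probabilities per row")
            rows.append([float(v) for v in vals])
            i += 1
        if len(rows) != width:
            err(matrix_line, f"motif {motif_id}: {len(rows)} rows but header declares w= {width}")
        probs = np.array(rows).T  # rows are positions; we store 4 x W
        sums = probs.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-3):
            err(matrix_line, f"motif {motif_id}: matrix columns do not sum to 1")
        probs = probs / sums
        motifs.append(
            MotifRecord(
                id=motif_id,
                matrix=FrequencyMatrix(probs=probs),
                nsites=nsites,
                coverage=1.0,
            )
        )
    return motifs


# ---------------------------------------------------------------------------
# mutant probe design
# ---------------------------------------------------------------------------

def design_mutant_probe(
    pwm: FrequencyMatrix, site: str
) -> tuple[str, list[int]]:
    """Mutate the two most conserved positions of a binding site.

    Selects the two positions with the highest information content
    (ties broken leftmost) and applies the transition substitutions
    G<->A and C<->T there — purine stays purine, pyrimidine stays
    pyrimidine, so probe geometry is minimally perturbed while the
    recognised bases are destroyed.  Applying the rule twice restores
    the original site.
    """
    if pwm.width < 2:
        raise ValueError("probe design needs motif width >= 2")
    site = site.upper()
    if len(site) != pwm.width:
        raise ValueError(f"site length {len(site)} != motif width {pwm.width}")
    if any(ch not in _TRANSITION for ch in site):
        raise ValueError("site must contain only A, C, G, T")
    ic = information_content(pwm).values
    # stable selection: highest IC first, leftmost wins ties
    order = sorted(range(pwm.width), key=lambda j: (-ic[j], j))
    positions = sorted(order[:2])
    chars = list(site)
    for j in positions:
        chars[j] = _TRANSITION[chars[j]]
    return "".join(chars), positions
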