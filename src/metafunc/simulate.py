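"""Synthetic gnotobiotic-community generator with known ground truth.

The simulator emulates the data shape of a defined-flora mouse gut
experiment: a small bacterial consortium (default: an eight-species
community modelled on the Altered Schaedler Flora, dominated by a
Bacteroidetes member) is transcribed into a reference set of transcripts
with planted gene families, COG letters and EC numbers; short single-end
reads are then drawn as a mixture of adaptor contamination, rRNA, host
(mouse) RNA and bacterial mRNA, with a two-level quality profile (good
bases plus a low-quality 3' tail).

Homology search is never run: :func:`simulate_hits` emits the alignment
evidence (BLAST tabular and SAM mapping reports) directly from the truth
table, optionally with spurious hits, so classification and clustering can
be tested against a known answer without external binaries or databases.

All randomness flows from the spec/function seeds; outputs are
deterministic and byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .readqc import ReadRecord

BASES = np.array(list("ACGT"))

# Illumina TruSeq-style adaptor used for contaminated reads
DEFAULT_ADAPTOR = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"


@dataclass(frozen=True)
class TaxonSpec:
    name: str
    phylum: str
    family: str
    abundance: float


#: Eight-species community modelled on the Altered Schaedler Flora, with a
#: Bacteroidetes member (Parabacteroides) dominant as observed in vivo.
ASF_LIKE_TAXA = (
    TaxonSpec("Parabacteroides_distasonis", "Bacteroidetes", "Porphyromonadaceae", 0.45),
    TaxonSpec("Clostridium_sp_ASF500", "Firmicutes", "Lachnospiraceae", 0.15),
    TaxonSpec("Clostridium_sp_ASF502", "Firmicutes", "Lachnospiraceae", 0.12),
    TaxonSpec("Fusiform_sp_ASF356", "Firmicutes", "Clostridiaceae", 0.10),
    TaxonSpec("Eubacterium_plexicaudatum", "Firmicutes", "Lachnospiraceae", 0.08),
    TaxonSpec("Lactobacillus_acidophilus", "Firmicutes", "Lactobacillaceae", 0.04),
    TaxonSpec("Lactobacillus_murinus", "Firmicutes", "Lactobacillaceae", 0.03),
    TaxonSpec("Mucispirillum_schaedleri", "Deferribacteres", "Deferribacteraceae", 0.03),
)

COG_LETTER_POOL = ("C", "E", "G", "J", "K", "L", "M", "P", "T", "EG", "KT")
EC_POOL = ("3.2.1.23", "2.3.3.13", "6.3.4.4", "2.6.1.1", "1.1.1.21", "2.7.1.69")


@dataclass(frozen=True)
class CommunitySpec:
    """Study conditions for one synthetic sample.

    Fractions follow the yields seen in quality-filtered mouse gut
    metatranscriptomes: roughly a fifth adaptor contamination, half rRNA,
    a small host component, the remainder bacterial mRNA. Reads are 76 nt
    with a low-quality 3' tail that the QC stage trims.
    """

    taxa: Sequence[TaxonSpec] = ASF_LIKE_TAXA
    transcripts_per_taxon: int = 40
    length_range: tuple[int, int] = (200, 1500)
    rrna_fraction: float = 0.53
    host_fraction: float = 0.06
    adaptor_fraction: float = 0.23
    nt_mappable_fraction: float = 0.05  # of bacterial mRNA reads, mapped at nt level
    read_length: int = 76
    n_reads: int = 20_000
    quality_good: int = 35
    quality_bad: int = 2
    bad_tail_len: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        mrna = 1.0 - self.rrna_fraction - self.host_fraction - self.adaptor_fraction
        if mrna <= 0:
            raise ValueError("adaptor + rrna + host fractions must leave room for bacterial mRNA")
        if abs(sum(t.abundance for t in self.taxa) - 1.0) > 1e-9:
            raise ValueError("taxon abundances must sum to 1")
        if self.length_range[0] < self.read_length:
            raise ValueError("minimum transcript length must cover the read length")

    @property
    def mrna_fraction(self) -> float:
        return 1.0 - self.rrna_fraction - self.host_fraction - self.adaptor_fraction


@dataclass
class SyntheticCommunity:
    spec: CommunitySpec
    reads: list[ReadRecord]
    transcripts: pd.DataFrame  # transcript_id, taxon, family_id, length, cog, ec
    sequences: dict[str, str]
    read_truth: pd.DataFrame  # read_id, category, transcript_id, taxon
    adaptors: list[str] = field(default_factory=lambda: [DEFAULT_ADAPTOR])

    @property
    def family_map(self) -> dict[str, str]:
        return dict(zip(self.transcripts["transcript_id"], self.transcripts["family_id"]))


def _random_seq(rng: np.random.Generator, length: int, probs: np.ndarray) -> str:
    return "".join(rng.choice(BASES, size=length, p=probs))


def _mutate(rng: np.random.Generator, seq: str, rate: float = 0.05) -> str:
    arr = np.array(list(seq))
    hits = rng.random(len(arr)) < rate
    arr[hits] = rng.choice(BASES, size=int(hits.sum()))
    return "".join(arr)


def _adaptor_index():
    from .readqc import AdaptorIndex

    return AdaptorIndex([DEFAULT_ADAPTOR], 16)


def _scrubbed(make, index) -> str:
    """Regenerate a sequence until it carries no chance adaptor match.

    Non-adaptor reads and reference transcripts must be identifiable as
    such: a random 16-mer matching the adaptor at <=1 mismatch (expected
    about once per 1e5 reads) would otherwise be a planted contradiction
    in the truth table.
    """
    for _ in range(20):
        seq = make()
        if not index.matches(seq):
            return seq
    raise RuntimeError("could not generate an adaptor-free sequence")


def simulate_community(spec: CommunitySpec) -> SyntheticCommunity:
    """Generate reference transcripts, reads and the truth table for a spec.

    Transcripts within a planted gene family are mutated copies of a
    common ancestor, so families are genuine sequence-sharing groups; the
    per-taxon base composition is biased (Dirichlet-drawn) so taxa are
    compositionally distinct. Read categories, source transcripts and
    positions are all recorded in the truth table.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    adaptor_index = _adaptor_index()

    # Fixed length ladder shared by every taxon: with identical length
    # multisets, per-taxon mean transcript length cancels out of RPKM
    # shares, so taxon-level RPKM mass recovers the spec abundances.
    length_grid = np.linspace(lo, hi, spec.transcripts_per_taxon).round().astype(int)

    # --- reference transcripts with planted families ---------------------
    t_rows = []
    sequences: dict[str, str] = {}
    fam_counter = 0
    for taxon in spec.taxa:
        probs = rng.dirichlet(np.full(4, 8.0))
        remaining = spec.transcripts_per_taxon
        t_index = 0
        while remaining > 0:
            fam_counter += 1
            fam_id = f"pf{fam_counter:04d}"
            size = min(int(rng.integers(1, 6)), remaining)
            member_lengths = length_grid[t_index : t_index + size]
            ancestor = _random_seq(rng, int(member_lengths.max()), probs)
            for length in member_lengths:
                t_index += 1
                tid = f"{taxon.name}_t{t_index:03d}"
                sequences[tid] = _scrubbed(
                    lambda: _mutate(rng, ancestor)[: int(length)], adaptor_index
                )
                t_rows.append(
                    {
                        "transcript_id": tid,
                        "taxon": taxon.name,
                        "family_id": fam_id,
                        "length": int(length),
                        "cog": str(rng.choice(COG_LETTER_POOL)),
                        "ec": str(rng.choice(EC_POOL)) if rng.random() < 0.5 else "",
                    }
                )
            remaining -= size
    transcripts = pd.DataFrame(t_rows)

    # --- reads ------------------------------------------------------------
    categories = np.array(["adaptor", "rrna", "mouse_tx", "mouse_genome", "bact_nt", "bact_peptide"])
    host_tx = spec.host_fraction / 3.0  # genome hits outnumber transcript hits ~2:1
    p = np.array(
        [
            spec.adaptor_fraction,
            spec.rrna_fraction,
            host_tx,
            spec.host_fraction - host_tx,
            spec.mrna_fraction * spec.nt_mappable_fraction,
            spec.mrna_fraction * (1.0 - spec.nt_mappable_fraction),
        ]
    )
    draw = rng.choice(len(categories), size=spec.n_reads, p=p / p.sum())
    taxon_names = [t.name for t in spec.taxa]
    taxon_p = np.array([t.abundance for t in spec.taxa])

    # mRNA reads: taxon by abundance, transcript by length share within the
    # taxon (fragmentation yields reads in proportion to transcript length);
    # the per-taxon read marginal is exactly the spec abundance
    abundance_of = {t.name: t.abundance for t in spec.taxa}
    tx_ids = transcripts["transcript_id"].to_numpy()
    tx_len = transcripts["length"].to_numpy(dtype=float)
    tax_len_sum = transcripts.groupby("taxon")["length"].transform("sum").to_numpy(dtype=float)
    tx_probs = (
        transcripts["taxon"].map(abundance_of).to_numpy(dtype=float) * tx_len / tax_len_sum
    )
    tx_probs = tx_probs / tx_probs.sum()
    n_bact = int(np.isin(draw, [4, 5]).sum())
    bact_tx_draws = iter(rng.choice(len(tx_ids), size=n_bact, p=tx_probs))
    n_rrna = int((draw == 1).sum())
    rrna_taxon_draws = iter(rng.choice(len(taxon_names), size=n_rrna, p=taxon_p))
    taxon_of_tx = dict(zip(transcripts["transcript_id"], transcripts["taxon"]))

    background = np.full(4, 0.25)
    good = spec.quality_good
    quals_template = [good] * (spec.read_length - spec.bad_tail_len) + [
        spec.quality_bad
    ] * spec.bad_tail_len

    reads: list[ReadRecord] = []
    truth_rows = []
    for i in range(spec.n_reads):
        read_id = f"r{i:07d}"
        category = categories[draw[i]]
        transcript_id = ""
        taxon = ""
        if category == "adaptor":
            seq = _random_seq(rng, spec.read_length, background)
            pos = int(rng.integers(0, spec.read_length - len(DEFAULT_ADAPTOR) + 1))
            seq = seq[:pos] + DEFAULT_ADAPTOR + seq[pos + len(DEFAULT_ADAPTOR) :]
        elif category in ("rrna", "mouse_tx", "mouse_genome"):
            if category == "rrna":
                taxon = taxon_names[int(next(rrna_taxon_draws))]
            seq = _scrubbed(
                lambda: _random_seq(rng, spec.read_length, background), adaptor_index
            )
        else:  # bacterial mRNA
            transcript_id = str(tx_ids[int(next(bact_tx_draws))])
            taxon = taxon_of_tx[transcript_id]
            src = sequences[transcript_id]
            start = int(rng.integers(0, len(src) - spec.read_length + 1))
            seq = src[start : start + spec.read_length]
        reads.append(ReadRecord(read_id, seq, tuple(quals_template)))
        truth_rows.append(
            {"read_id": read_id, "category": category, "transcript_id": transcript_id, "taxon": taxon}
        )

    return SyntheticCommunity(
        spec=spec,
        reads=reads,
        transcripts=transcripts,
        sequences=sequences,
        read_truth=pd.DataFrame(truth_rows),
    )


@dataclass(frozen=True)
class HitNoise:
    identity_mean: float = 97.0
    identity_sd: float = 1.5
    spurious_rate: float = 0.0
    #: probability that a spurious hit clears its stream's threshold
    spurious_pass: float = 0.2


@dataclass
class Evidence:
    """Alignment evidence for one sample, as the classifier consumes it."""

    rrna_hits: pd.DataFrame  # BLAST tabular columns
    peptide_hits: pd.DataFrame
    allvall_hits: pd.DataFrame
    mouse_tx_mapped: set[str]
    mouse_genome_mapped: set[str]
    bact_nt_mapped: set[str]
    rrna_taxonomy: dict[str, str]  # rRNA subject id -> family-level taxon


def _b6_row(q: str, s: str, pident: float, length: int, evalue: float, bits: float) -> dict:
    return {
        "qseqid": q,
        "sseqid": s,
        "pident": round(pident, 2),
        "length": length,
        "mismatch": max(0, int(length * (100.0 - pident) / 100.0)),
        "gapopen": 0,
        "qstart": 1,
        "qend": length,
        "sstart": 1,
        "send": length,
        "evalue": evalue,
        "bitscore": round(bits, 1),
    }


def simulate_hits(
    community: SyntheticCommunity,
    noise: HitNoise = HitNoise(),
    seed: int | None = None,
) -> Evidence:
    """Emit alignment evidence from the truth table.

    True-origin hits score well above every classification threshold
    (rRNA bit scores ~80-120, peptide identities ~97% over ~90% of the
    high-quality read length, family hits at E ~ 1e-30). Spurious hits are
    injected per read at ``noise.spurious_rate``; most fall below the
    relevant cutoff and only a ``spurious_pass`` fraction can flip a
    read's category.
    """
    spec = community.spec
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    phylum = {t.name: t for t in spec.taxa}
    aa_len = max(1, int((spec.read_length - spec.bad_tail_len) * 0.9 / 3.0))

    rrna_rows, pep_rows = [], []
    mouse_tx, mouse_genome, bact_nt = set(), set(), set()
    rrna_taxonomy = {f"SSU_{t.name}": phylum[t.name].family for t in spec.taxa}

    for row in community.read_truth.itertuples(index=False):
        if row.category == "rrna":
            bits = float(rng.uniform(80, 120))
            rrna_rows.append(
                _b6_row(row.read_id, f"SSU_{row.taxon}", 99.0, spec.read_length, 1e-30, bits)
            )
        elif row.category == "mouse_tx":
            mouse_tx.add(row.read_id)
        elif row.category == "mouse_genome":
            mouse_genome.add(row.read_id)
        elif row.category == "bact_nt":
            bact_nt.add(row.read_id)
        elif row.category == "bact_peptide":
            pident = float(np.clip(rng.normal(noise.identity_mean, noise.identity_sd), 90.0, 100.0))
            pep_rows.append(
                _b6_row(row.read_id, row.transcript_id, pident, aa_len, 1e-20, 110.0)
            )
        # adaptor reads leave no alignment evidence

    # spurious evidence: mostly sub-threshold, occasionally category-flipping
    n_spurious = rng.binomial(spec.n_reads, noise.spurious_rate) if noise.spurious_rate else 0
    if n_spurious:
        victims = rng.choice(spec.n_reads, size=n_spurious, replace=False)
        for idx in victims:
            read_id = f"r{int(idx):07d}"
            passing = rng.random() < noise.spurious_pass
            if rng.random() < 0.5:
                bits = float(rng.uniform(51, 70)) if passing else float(rng.uniform(20, 50))
                rrna_rows.append(
                    _b6_row(read_id, "SSU_spurious", 80.0, spec.read_length, 1e-3, bits)
                )
                rrna_taxonomy.setdefault("SSU_spurious", "Other")
            else:
                pident = float(rng.uniform(85, 95)) if passing else float(rng.uniform(40, 70))
                tid = community.transcripts["transcript_id"].iat[
                    int(rng.integers(0, len(community.transcripts)))
                ]
                pep_rows.append(_b6_row(read_id, tid, pident, aa_len, 5e-2, 40.0))

    # all-vs-all transcript similarity: hits within planted families only
    av_rows = []
    for _, group in community.transcripts.groupby("family_id"):
        members = group["transcript_id"].to_list()
        length = int(group["length"].iat[0])
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                bits = float(rng.uniform(150, 400))
                av_rows.append(_b6_row(a, b, 95.0, length, 1e-30, bits))
                av_rows.append(_b6_row(b, a, 95.0, length, 1e-30, bits))
    if noise.spurious_rate:
        tids = community.transcripts["transcript_id"].to_list()
        n_cross = rng.binomial(len(av_rows) + 1, noise.spurious_rate)
        for _ in range(n_cross):
            a, b = rng.choice(tids, size=2, replace=False)
            # cross-family noise stays above the E-value cutoff
            av_rows.append(_b6_row(str(a), str(b), 60.0, 40, 1e-3, 35.0))

    from .io import BLAST6_COLUMNS

    empty = pd.DataFrame(columns=BLAST6_COLUMNS)
    return Evidence(
        rrna_hits=pd.DataFrame(rrna_rows) if rrna_rows else empty.copy(),
        peptide_hits=pd.DataFrame(pep_rows) if pep_rows else empty.copy(),
        allvall_hits=pd.DataFrame(av_rows) if av_rows else empty.copy(),
        mouse_tx_mapped=mouse_tx,
        mouse_genome_mapped=mouse_genome,
        bact_nt_mapped=bact_nt,
        rrna_taxonomy=rrna_taxonomy,
    )


def write_community(community: SyntheticCommunity, evidence: Evidence, outdir: str | Path) -> dict[str, Path]:
    """Write reads, references and evidence to standard files; returns paths."""
    from . import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reads": outdir / "reads.fastq",
        "adaptors": outdir / "adaptors.fasta",
        "transcripts": outdir / "transcripts.fasta",
        "truth": outdir / "read_truth.tsv",
        "transcript_table": outdir / "transcripts.tsv",
        "rrna_hits": outdir / "rrna.b6",
        "peptide_hits": outdir / "peptide.b6",
        "allvall_hits": outdir / "allvall.b6",
        "mouse_tx": outdir / "mouse_tx.sam",
        "mouse_genome": outdir / "mouse_genome.sam",
        "bact_nt": outdir / "bact_genomes.sam",
    }
    io.write_fastq(community.reads, paths["reads"])
    io.write_fasta({f"adaptor_{i}": a for i, a in enumerate(community.adaptors)}, paths["adaptors"])
    io.write_fasta(community.sequences, paths["transcripts"])
    community.read_truth.to_csv(paths["truth"], sep="\t", index=False)
    community.transcripts.to_csv(paths["transcript_table"], sep="\t", index=False)
    io.write_blast_tabular(evidence.rrna_hits, paths["rrna_hits"])
    io.write_blast_tabular(evidence.peptide_hits, paths["peptide_hits"])
    io.write_blast_tabular(evidence.allvall_hits, paths["allvall_hits"])
    io.write_sam(sorted(evidence.mouse_tx_mapped), {"mm_transcripts": 10_000}, paths["mouse_tx"])
    io.write_sam(sorted(evidence.mouse_genome_mapped), {"mm_genome": 100_000}, paths["mouse_genome"])
    io.write_sam(sorted(evidence.bact_nt_mapped), {"bact_pan": 100_000}, paths["bact_nt"])
    return paths
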