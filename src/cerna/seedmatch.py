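"""Canonical miRNA seed-site scanning and classification.

A canonical site is a perfect Watson-Crick match on the target transcript
to the miRNA seed region (nucleotides 2-7 or 2-8 counted from the miRNA
5' end), read antiparallel. Four site types are recognized, in decreasing
predicted efficacy:

    8mer      match to nt 2-8 plus an A opposite miRNA nt 1
    7mer-m8   match to nt 2-8
    7mer-A1   match to nt 2-7 plus the 3' A
    6mer      match to nt 2-7 only

Only these canonical types are scanned; no GU wobble, 3'-supplementary
pairing, or context scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
SITE_PRIORITY = {t: i for i, t in enumerate(SITE_TYPES)}  # lower = stronger
NO_SITE = "no binding site"

_RNA_TO_DNA_COMPLEMENT = str.maketrans("ACGU", "TGCA")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SequenceError(ValueError):
    """Invalid sequence input."""


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA sequence, 5'->3', RNA alphabet, 1-based positions."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 8:
            raise SequenceError(f"{self.id}: mature sequence shorter than 8 nt")
        bad = set(seq) - set("ACGU")
        if bad:
            raise SequenceError(f"{self.id}: non-RNA characters {sorted(bad)}")


@dataclass(frozen=True)
class SeedSite:
    """One classified site: 1-based closed interval on the transcript."""

    transcript_id: str
    mirna_id: str
    start: int
    end: int
    site_type: str


def _revcomp_rna_to_dna(rna: str) -> str:
    return rna.translate(_RNA_TO_DNA_COMPLEMENT)[::-1]


def seed_patterns(mirna: MatureMiRNA) -> dict[str, str]:
    """Target-site motifs (DNA sense strand) for each canonical site type.

    The 6mer core is the reverse complement of seed nt 2-7; the m8 match
    prepends the complement of nt 8; the A1 anchor appends an A regardless
    of miRNA nt 1 identity.
    """
    seq = mirna.sequence
    core = _revcomp_rna_to_dna(seq[1:7])      # nt 2-7
    with_m8 = _revcomp_rna_to_dna(seq[1:8])   # nt 2-8
    return {
        "8mer": with_m8 + "A",
        "7mer-m8": with_m8,
        "7mer-A1": core + "A",
        "6mer": core,
    }


def normalize_transcript(seq: str) -> str:
    """Uppercase and collapse RNA to DNA alphabet (U -> T)."""
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise SequenceError(f"non-nucleotide characters {sorted(bad)}")
    return seq


def scan_transcript(mirna: MatureMiRNA, transcript: str,
                    transcript_id: str = "") -> list[SeedSite]:
    """All canonical sites of ``mirna`` on a transcript sequence.

    Each occurrence of the 6mer seed core is reported exactly once, under
    the highest-priority site type whose motif matches at that locus
    (8mer > 7mer-m8 > 7mer-A1 > 6mer). Coordinates are 1-based closed
    intervals covering the matched motif.
    """
    seq = normalize_transcript(transcript)
    pats = seed_patterns(mirna)
    core = pats["6mer"]
    m8_base = pats["7mer-m8"][0]
    sites: list[SeedSite] = []
    start = seq.find(core)
    while start != -1:
        has_m8 = start >= 1 and seq[start - 1] == m8_base
        has_a1 = start + 6 < len(seq) and seq[start + 6] == "A"
        if has_m8 and has_a1:
            site = ("8mer", start - 1, start + 6)
        elif has_m8:
            site = ("7mer-m8", start - 1, start + 5)
        elif has_a1:
            site = ("7mer-A1", start, start + 6)
        else:
            site = ("6mer", start, start + 5)
        stype, s0, e0 = site
        sites.append(SeedSite(transcript_id, mirna.id, s0 + 1, e0 + 1, stype))
        start = seq.find(core, start + 1)
    return sites


def best_site(sites: list[SeedSite]) -> SeedSite | None:
    """Strongest site by type priority, then leftmost position."""
    if not sites:
        return None
    return min(sites, key=lambda s: (SITE_PRIORITY[s.site_type], s.start))


def read_fasta(path) -> dict[str, str]:
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise SequenceError(f"duplicate FASTA id: {rec.id}")
        records[rec.id] = str(rec.seq)
    return records


def annotate_candidates(mirnas: list[MatureMiRNA], transcripts: dict[str, str]) -> pd.DataFrame:
    """Best canonical site per (miRNA, transcript).

    Returns one row for every combination; transcripts without any site for
    a miRNA carry ``site_type`` = "no binding site" with empty coordinates,
    mirroring how published binding-site tables list negative rows.
    """
    rows = []
    for mirna in mirnas:
        for tid, seq in transcripts.items():
            site = best_site(scan_transcript(mirna, seq, tid))
            if site is None:
                rows.append((mirna.id, tid, pd.NA, pd.NA, NO_SITE))
            else:
                rows.append((mirna.id, tid, site.start, site.end, site.site_type))
    return pd.DataFrame(
        rows, columns=["mirna_id", "transcript_id", "start", "end", "site_type"]
    )


def annotate_fasta(mirnas: list[MatureMiRNA], fasta_path) -> pd.DataFrame:
    return annotate_candidates(mirnas, read_fasta(fasta_path))
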