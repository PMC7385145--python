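"""Candidate-gene alignment statistics: haplotypes, diversity, substitutions.

Operates on per-gene nucleotide multiple alignments (equal-length sequences
over {A, C, G, T, N, -}) and reports the quantities usually tabulated for
candidate genes across a variety panel:

* **H** — number of distinct haplotypes. Missing-data policy: two sequences
  are compared only at sites where both are unambiguous (A/C/G/T); a
  sequence indistinguishable from an existing haplotype under this rule
  collapses into it (greedy, first match in input order), which mirrors how
  scaffold-level assemblies with gaps are grouped.
* **Pi** — nucleotide diversity: the mean over all unordered sequence pairs
  of (pairwise differences / pairwise comparable sites), sites with a gap
  or N in either sequence excluded pairwise. No multiple-hit correction is
  applied (intra-species, low-divergence data).
* **SS / NS** — synonymous / nonsynonymous substitution counts relative to
  a designated reference sequence, by standard-codon-table comparison of
  whole codons; each distinct (codon position, variant codon) pair counts
  once across the alignment. Codons interrupted by alignment gaps are
  skipped and tallied, and indels are counted as events rather than
  classified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq

__all__ = [
    "DiversityReport",
    "count_haplotypes",
    "nucleotide_diversity",
    "classify_substitutions",
    "SubstitutionSummary",
    "gene_report",
]

_UNAMBIGUOUS = frozenset("ACGT")


@dataclass
class SubstitutionSummary:
    synonymous: int
    nonsynonymous: int
    sites: pd.DataFrame  # codon_index, ref_codon, alt_codon, ref_aa, alt_aa, effect
    skipped_codons: int
    indel_events: int


@dataclass
class DiversityReport:
    gene: str
    n_sequences: int
    haplotypes: int
    synonymous: int
    nonsynonymous: int
    pi: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": self.gene,
                    "n_sequences": self.n_sequences,
                    "H": self.haplotypes,
                    "SS": self.synonymous,
                    "NS": self.nonsynonymous,
                    "Pi": self.pi,
                }
            ]
        )


def _to_strings(aln) -> list[tuple[str, str]]:
    if isinstance(aln, MultipleSeqAlignment):
        pairs = [(rec.id, str(rec.seq).upper()) for rec in aln]
    else:
        pairs = [(str(i), str(s).upper()) for i, s in aln]
    if not pairs:
        raise ValueError("alignment contains no sequences")
    length = len(pairs[0][1])
    for sid, s in pairs:
        if len(s) != length:
            raise ValueError(f"sequence {sid} has length {len(s)} != {length}")
        bad = set(s) - set("ACGTN-")
        if bad:
            raise ValueError(f"sequence {sid} contains invalid symbols {sorted(bad)}")
    return pairs


def _encode(pairs):
    """Byte-encode sequences; mask marks unambiguous A/C/G/T sites."""
    arr = np.array([np.frombuffer(s.encode(), dtype=np.uint8) for _, s in pairs])
    mask = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    return arr, mask


# ---------------------------------------------------------------------------


def count_haplotypes(aln) -> int:
    """Distinct-haplotype count under the pairwise missing-data policy."""
    pairs = _to_strings(aln)
    arr, mask = _encode(pairs)
    reps: list[int] = []  # indices of haplotype representatives
    for i in range(arr.shape[0]):
        matched = False
        for r in reps:
            both = mask[i] & mask[r]
            if not np.any(arr[i][both] != arr[r][both]):
                matched = True
                break
        if not matched:
            reps.append(i)
    return len(reps)


def nucleotide_diversity(aln) -> float:
    """Per-site nucleotide diversity Pi (NaN when no pair is comparable)."""
    pairs = _to_strings(aln)
    if len(pairs) < 2:
        raise ValueError("nucleotide diversity needs >= 2 sequences")
    arr, mask = _encode(pairs)
    n = arr.shape[0]
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            both = mask[i] & mask[j]
            m = int(both.sum())
            if m == 0:
                continue
            d = int(np.count_nonzero(arr[i][both] != arr[j][both]))
            vals.append(d / m)
    if not vals:
        warnings.warn("no comparable sites in any sequence pair; Pi undefined")
        return float("nan")
    return float(np.mean(vals))


def classify_substitutions(
    aln, reference_id: str | None = None, frame: int = 0
) -> SubstitutionSummary:
    """Synonymous/nonsynonymous classification against a reference sequence.

    ``frame`` is the 0-based offset of the first complete codon; a trailing
    partial codon is excluded with a warning. Variant codons are compared to
    the reference codon as whole codons (so multi-hit codons are classified
    once by their amino-acid change); codons containing gaps or ambiguous
    bases in a sequence are skipped for that sequence and tallied.
    """
    pairs = _to_strings(aln)
    ids = [sid for sid, _ in pairs]
    if reference_id is None:
        reference_id = ids[0]
    if reference_id not in ids:
        raise ValueError(f"reference sequence {reference_id!r} not in alignment")
    if not 0 <= frame <= 2:
        raise ValueError("frame must be 0, 1 or 2")
    seqs = dict(pairs)
    ref = seqs[reference_id]
    length = len(ref)
    n_codons = (length - frame) // 3
    if (length - frame) % 3:
        warnings.warn(
            f"terminal partial codon of {(length - frame) % 3} bases excluded"
        )

    seen: set[tuple[int, str]] = set()
    rows = []
    skipped = 0
    indels = 0
    for sid, s in pairs:
        if sid == reference_id:
            continue
        # count indel events: runs of '-' in either sequence relative to the other
        indels += _indel_events(ref, s)
        for ci in range(n_codons):
            start = frame + 3 * ci
            ref_codon = ref[start : start + 3]
            codon = s[start : start + 3]
            if codon == ref_codon:
                continue
            if not set(ref_codon) <= _UNAMBIGUOUS:
                skipped += 1
                continue
            if "-" in codon or not set(codon) <= _UNAMBIGUOUS:
                skipped += 1
                continue
            key = (ci, codon)
            if key in seen:
                continue
            seen.add(key)
            ref_aa = str(Seq(ref_codon).translate())
            alt_aa = str(Seq(codon).translate())
            rows.append(
                {
                    "codon_index": ci,
                    "ref_codon": ref_codon,
                    "alt_codon": codon,
                    "ref_aa": ref_aa,
                    "alt_aa": alt_aa,
                    "effect": "synonymous" if ref_aa == alt_aa else "nonsynonymous",
                }
            )
    sites = pd.DataFrame(
        rows,
        columns=["codon_index", "ref_codon", "alt_codon", "ref_aa", "alt_aa", "effect"],
    )
    ss = int((sites["effect"] == "synonymous").sum()) if len(sites) else 0
    ns = int((sites["effect"] == "nonsynonymous").sum()) if len(sites) else 0
    return SubstitutionSummary(
        synonymous=ss,
        nonsynonymous=ns,
        sites=sites.sort_values("codon_index").reset_index(drop=True),
        skipped_codons=skipped,
        indel_events=indels,
    )


def _indel_events(a: str, b: str) -> int:
    """Count maximal gap runs present in exactly one of the two sequences."""
    events = 0
    in_run = False
    for ca, cb in zip(a, b):
        gap = (ca == "-") != (cb == "-")
        if gap and not in_run:
            events += 1
        in_run = gap
    return events


def gene_report(gene: str, aln, reference_id: str | None = None, frame: int = 0) -> DiversityReport:
    """Full per-gene summary: H, SS, NS and Pi."""
    pairs = _to_strings(aln)
    subs = classify_substitutions(aln, reference_id=reference_id, frame=frame)
    return DiversityReport(
        gene=gene,
        n_sequences=len(pairs),
        haplotypes=count_haplotypes(aln),
        synonymous=subs.synonymous,
        nonsynonymous=subs.nonsynonymous,
        pi=nucleotide_diversity(aln) if len(pairs) >= 2 else float("nan"),
    )
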