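"""Strain-level demultiplexing of merged amplicon reads.

Invading populations are mixtures of strains of a single species, told apart
by strain-diagnostic marker amplicons.  A read is assigned to a strain if and
only if it equals one of that strain's expected PCR-product sequences exactly
— full length, 100% identity — in either orientation.  Counts are converted
to relative shares; the share table at the invasion day serves as the DNA
amount baseline, and the per-strain gain or loss of share from baseline to
the experiment end is the measurement of strain-specific invasion success.

Strains whose amplicons cannot be discriminated (indistinguishability
groups) have their counts pooled under a combined label whenever they were
co-introduced into the same mixture.  A mixture in which a designed strain
is undetected at baseline is excluded from downstream analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")

BASELINE = "baseline"
END = "end"

#: end-of-experiment share above which a strain is called dominant in a mixture
DOMINANCE_THRESHOLD = 0.66


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def combined_label(strains: Iterable[str]) -> str:
    """Pooled label for indistinguishable co-introduced strains."""
    return " and ".join(sorted(strains))


# ---------------------------------------------------------------------------
# Marker database
# ---------------------------------------------------------------------------


@dataclass
class MarkerDB:
    """Per-strain unique expected PCR-product sequences.

    Parameters
    ----------
    records
        Mapping strain_id -> list of marker sequences (uppercase A/C/G/T).
        A strain may carry several markers; counts are summed over them.
    groups
        Sets of strain ids that are mutually indistinguishable when
        co-introduced (their shares cannot be separated and are pooled).
    """

    records: dict[str, list[str]]
    groups: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for strain, seqs in self.records.items():
            if not seqs:
                raise ValueError(f"strain {strain!r} has no marker sequence")
            for s in seqs:
                if not s:
                    raise ValueError(f"empty marker sequence for {strain!r}")
                if set(s) - set("ACGT"):
                    raise ValueError(
                        f"marker for {strain!r} contains non-ACGT characters"
                    )
                owner = seen.get(s)
                if owner is not None and owner != strain:
                    if not self._same_group(owner, strain):
                        raise ValueError(
                            f"marker sequence shared by non-grouped strains "
                            f"{owner!r} and {strain!r}"
                        )
                seen[s] = strain
        members = [s for g in self.groups for s in g]
        if len(members) != len(set(members)):
            raise ValueError("a strain appears in more than one group")

    def _same_group(self, a: str, b: str) -> bool:
        return any(a in g and b in g for g in self.groups)

    @property
    def strains(self) -> list[str]:
        return sorted(self.records)

    def lookup_table(self) -> dict[str, str]:
        """Exact-match table: sequence (fwd and revcomp) -> strain label.

        A sequence carried by several strains of one group maps to the
        group's combined label directly, since such a read cannot be
        attributed to an individual strain.
        """
        by_seq: dict[str, set[str]] = {}
        for strain, seqs in self.records.items():
            for s in seqs:
                by_seq.setdefault(s, set()).add(strain)
        table: dict[str, str] = {}
        for s, owners in by_seq.items():
            label = next(iter(owners)) if len(owners) == 1 else combined_label(owners)
            table[s] = label
            table[reverse_complement(s)] = label
        return table

    def group_for(self, strain: str) -> frozenset[str] | None:
        for g in self.groups:
            if strain in g:
                return g
        return None

    @classmethod
    def from_fasta(cls, path: str | Path) -> "MarkerDB":
        """Read a marker FASTA.

        The record id is the strain id; an optional ``;group=NAME`` tag on
        the id declares membership in an indistinguishability group (all
        records sharing a NAME form one group).
        """
        records: dict[str, list[str]] = {}
        group_names: dict[str, set[str]] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            ident = rec.id
            group = None
            if ";group=" in ident:
                ident, group = ident.split(";group=", 1)
            records.setdefault(ident, []).append(str(rec.seq).upper())
            if group:
                group_names.setdefault(group, set()).add(ident)
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        groups = [frozenset(m) for m in group_names.values() if len(m) > 1]
        return cls(records=records, groups=groups)

    def to_fasta(self, path: str | Path) -> None:
        name_of = {}
        for i, g in enumerate(self.groups, start=1):
            for s in g:
                name_of[s] = f"g{i}"
        with open(path, "w") as fh:
            for strain in self.strains:
                tag = f";group={name_of[strain]}" if strain in name_of else ""
                for seq in self.records[strain]:
                    fh.write(f">{strain}{tag}\n{seq}\n")


# ---------------------------------------------------------------------------
# Counting and shares
# ---------------------------------------------------------------------------


@dataclass
class StrainCounts:
    """Exact-match read counts ("abundance") per strain or group label."""

    sample_id: str
    counts: dict[str, int]
    n_reads_total: int
    n_unmatched: int
    cross_hits: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative count")
        if sum(self.counts.values()) + self.n_unmatched != self.n_reads_total:
            raise ValueError("counts + unmatched must equal total reads")

    @property
    def n_matched(self) -> int:
        return self.n_reads_total - self.n_unmatched


@dataclass
class ShareTable:
    """Relative strain shares for one sample at one timepoint.

    Shares sum to 1 when any read matched; a sample with zero matched reads
    is flagged ``undefined`` and carries no shares.
    """

    sample_id: str
    timepoint: str
    shares: dict[str, float]
    undefined: bool = False

    def __post_init__(self) -> None:
        if self.timepoint not in (BASELINE, END):
            raise ValueError(f"timepoint must be {BASELINE!r} or {END!r}")
        if not self.undefined and self.shares:
            total = sum(self.shares.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"shares sum to {total}, expected 1")


@dataclass
class GainLossTable:
    """Per-strain change in share from baseline to end for one mixture."""

    mixture_id: str
    delta: dict[str, float]
    dominant: set[str] = field(default_factory=set)
    excluded: bool = False
    reason: str | None = None


def match_reads(
    reads: Iterable[str],
    db: MarkerDB,
    sample_id: str = "",
    allow_rc: bool = True,
    design_strains: set[str] | None = None,
) -> StrainCounts:
    """Score reads against the marker database by exact full-length match.

    A read is scored for a marker iff the read — or, with ``allow_rc``, its
    reverse complement — equals the marker exactly (same length, 100%
    identity).  Everything else, including reads containing ``N`` or other
    non-ACGT characters, is counted unmatched.  If ``design_strains`` is
    given, hits on markers of strains outside that set (whose primers were
    not used in the sample's experiment) are additionally reported in
    ``cross_hits`` as a cross-contamination diagnostic.
    """
    table = db.lookup_table()
    if not allow_rc:
        table = {s: lab for s, lab in table.items() if s in
                 {m for seqs in db.records.values() for m in seqs}}
    counts: dict[str, int] = {}
    n_total = 0
    n_unmatched = 0
    n_bad = 0
    for read in reads:
        n_total += 1
        r = str(read).upper()
        label = table.get(r)
        if label is None:
            if set(r) - _VALID_BASES:
                n_bad += 1
            n_unmatched += 1
            continue
        counts[label] = counts.get(label, 0) + 1
    if n_bad:
        logger.warning(
            "%s: %d read(s) with characters outside {A,C,G,T,N} counted unmatched",
            sample_id or "<sample>", n_bad,
        )
    cross: dict[str, int] = {}
    if design_strains is not None:
        designed_labels = set(design_strains)
        for g in db.groups:
            if len(g & designed_labels) >= 2:
                designed_labels.add(combined_label(g & designed_labels))
        cross = {lab: c for lab, c in counts.items() if lab not in designed_labels}
        if cross:
            logger.warning("%s: cross-contamination hits %s", sample_id, cross)
    return StrainCounts(
        sample_id=sample_id,
        counts=counts,
        n_reads_total=n_total,
        n_unmatched=n_unmatched,
        cross_hits=cross,
    )


def collapse_groups(
    counts: StrainCounts, design_strains: set[str], db: MarkerDB
) -> StrainCounts:
    """Pool counts of indistinguishable strains that were co-introduced.

    For each group of the database with at least two members in the
    mixture's design, member counts merge under the combined label; groups
    with a single designed member are left as individual strains.  The total
    matched count is preserved.
    """
    merged = dict(counts.counts)
    for g in db.groups:
        present = sorted(g & set(design_strains))
        if len(present) < 2:
            continue
        label = combined_label(present)
        pooled = merged.pop(label, 0)
        for s in present:
            pooled += merged.pop(s, 0)
        merged[label] = pooled
    return StrainCounts(
        sample_id=counts.sample_id,
        counts=merged,
        n_reads_total=counts.n_reads_total,
        n_unmatched=counts.n_unmatched,
        cross_hits=counts.cross_hits,
    )


def design_labels(design_strains: Iterable[str], db: MarkerDB) -> set[str]:
    """Strain-or-group labels expected after collapsing for this design."""
    labels = set(design_strains)
    for g in db.groups:
        present = sorted(g & labels)
        if len(present) >= 2:
            labels -= set(present)
            labels.add(combined_label(present))
    return labels


def relative_shares(
    counts: StrainCounts, timepoint: str, labels: Iterable[str] | None = None
) -> ShareTable:
    """Counts -> relative shares; share(s) = count(s) / total matched.

    ``labels`` fixes the label universe (e.g. the designed strains after
    collapsing) so that undetected strains appear with share 0.  A sample
    with no matched reads at all is flagged undefined.
    """
    universe = set(labels) if labels is not None else set(counts.counts)
    relevant = {lab: counts.counts.get(lab, 0) for lab in universe}
    total = sum(relevant.values())
    if total == 0:
        logger.warning("%s: no matched reads, shares undefined", counts.sample_id)
        return ShareTable(counts.sample_id, timepoint, {}, undefined=True)
    shares = {lab: c / total for lab, c in relevant.items()}
    return ShareTable(counts.sample_id, timepoint, shares)


def strain_gain_loss(
    baseline: ShareTable,
    end: ShareTable,
    mixture_id: str | None = None,
    dominance_threshold: float = DOMINANCE_THRESHOLD,
) -> GainLossTable:
    """Change in share per strain/group: Δshare = end − baseline.

    Labels missing at one timepoint enter with share 0 there, so the deltas
    of a mixture sum to zero whenever both timepoints are defined.  Strains
    whose end share exceeds the dominance threshold are flagged dominant.
    """
    if mixture_id is None:
        mixture_id = baseline.sample_id
    if baseline.timepoint != BASELINE or end.timepoint != END:
        raise ValueError("expected a baseline table and an end table")
    if baseline.undefined or end.undefined:
        return GainLossTable(
            mixture_id, {}, excluded=True,
            reason="undefined shares at one or both timepoints",
        )
    labels = set(baseline.shares) | set(end.shares)
    delta = {
        lab: end.shares.get(lab, 0.0) - baseline.shares.get(lab, 0.0)
        for lab in labels
    }
    dominant = {
        lab for lab, s in end.shares.items() if s > dominance_threshold
    }
    return GainLossTable(mixture_id, delta, dominant=dominant)


def exclude_undetected(
    design_strains: Iterable[str], baseline: ShareTable, db: MarkerDB
) -> tuple[bool, str | None]:
    """Exclusion rule: drop a mixture if a designed strain is absent at baseline.

    Applied after group collapsing; a mixture is excluded iff any designed
    strain-or-group label has baseline share 0 (or the baseline sample had
    no matched reads at all).
    """
    expected = design_labels(design_strains, db)
    if baseline.undefined:
        return True, "no strain detected at baseline"
    missing = sorted(
        lab for lab in expected if baseline.shares.get(lab, 0.0) == 0.0
    )
    if missing:
        return True, f"{', '.join(missing)} undetected at baseline"
    return False, None


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def load_reads(path: str | Path) -> list[str]:
    """Read merged amplicon reads from FASTA or FASTQ (by extension)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), fmt)]


def shares_to_frame(tables: Sequence[ShareTable]) -> pd.DataFrame:
    rows = []
    for t in tables:
        if t.undefined:
            rows.append(
                {"sample_id": t.sample_id, "timepoint": t.timepoint,
                 "strain": None, "share": None}
            )
        for strain, share in sorted(t.shares.items()):
            rows.append(
                {"sample_id": t.sample_id, "timepoint": t.timepoint,
                 "strain": strain, "share": share}
            )
    return pd.DataFrame(rows, columns=["sample_id", "timepoint", "strain", "share"])


def counts_to_frame(all_counts: Sequence[StrainCounts]) -> pd.DataFrame:
    rows = []
    for c in all_counts:
        for strain, n in sorted(c.counts.items()):
            rows.append(
                {"sample_id": c.sample_id, "strain": strain, "count": n,
                 "n_reads_total": c.n_reads_total, "n_unmatched": c.n_unmatched}
            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "strain", "count", "n_reads_total", "n_unmatched"],
    )


def gainloss_to_frame(tables: Sequence[GainLossTable]) -> pd.DataFrame:
    rows = []
    for t in tables:
        if t.excluded:
            rows.append(
                {"mixture_id": t.mixture_id, "strain": None, "delta_share": None,
                 "dominant": False, "excluded": True, "reason": t.reason}
            )
            continue
        for strain, d in sorted(t.delta.items()):
            rows.append(
                {"mixture_id": t.mixture_id, "strain": strain, "delta_share": d,
                 "dominant": strain in t.dominant, "excluded": False,
                 "reason": None}
            )
    return pd.DataFrame(
        rows,
        columns=["mixture_id", "strain", "delta_share", "dominant",
                 "excluded", "reason"],
    )
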