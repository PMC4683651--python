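"""Strand-exchange (heteroduplex) tract mapping in DSB-repair recombinants.

Each sequenced molecule derives from a recipient parent that may carry a
contiguous run of donor-parent SNPs laid down during double-strand-break
repair (preserved when mismatch repair is off). Every panel SNP in every
read is classified as RECIPIENT, DONOR, ERROR (matches neither parent), or
MISSING; maximal donor runs of at least ``min_run`` sites are reported as
exchange tracts, while shorter donor runs are flagged as putative random
errors — an isolated discordant SNP is far more likely a sequencing error
than a one-SNP conversion tract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .align import AlignedRead
from .io import MISSING, ParentalPanel

RECIPIENT = "RECIPIENT"
DONOR = "DONOR"
ERROR = "ERROR"


@dataclass
class ReadClassification:
    """Per-site parental classification of one read."""

    read_id: str
    symbols: tuple[str, ...]  # RECIPIENT/DONOR/ERROR/MISSING per panel site
    tracts: tuple[tuple[int, int], ...]  # maximal DONOR runs (first, last), 0-based
    flagged_singletons: tuple[int, ...]  # donor runs below min_run, putative errors


@dataclass
class TractSummary:
    """Population summary over classified reads."""

    recipient: list[int]  # per-site counts
    donor: list[int]
    error: list[int]
    missing: list[int]
    flagged_singleton: list[int]  # subset of donor counts flagged as putative errors
    donor_fraction: list[float]
    error_fraction: list[float]  # background noise estimate per site
    # maximal run of sites whose donor fraction >= threshold, 0-based inclusive
    consensus_interval: Optional[tuple[int, int]]
    n_reads: int


def classify_read(
    alignment: AlignedRead,
    panel: ParentalPanel,
    min_run: int = 2,
) -> ReadClassification:
    """Classify every panel SNP of a read against the two parental alleles."""
    wanted = {site.position: i for i, site in enumerate(panel)}
    bases: list[str] = [MISSING] * len(panel)
    for ref_pos, read_pos, op in alignment.reference_columns():
        if op == "I":
            continue
        idx = wanted.get(ref_pos)
        if idx is None:
            continue
        bases[idx] = MISSING if op == "D" else alignment.sequence[read_pos]
    symbols: list[str] = []
    for site, base in zip(panel, bases):
        if base == MISSING:
            symbols.append(MISSING)
        elif base == site.recipient:
            symbols.append(RECIPIENT)
        elif base == site.donor:
            symbols.append(DONOR)
        else:
            symbols.append(ERROR)

    tracts: list[tuple[int, int]] = []
    flagged: list[int] = []
    i = 0
    while i < len(symbols):
        if symbols[i] != DONOR:
            i += 1
            continue
        j = i
        while j < len(symbols) and symbols[j] == DONOR:
            j += 1
        if j - i >= min_run:
            tracts.append((i, j - 1))
        else:
            flagged.extend(range(i, j))
        i = j
    return ReadClassification(
        read_id=alignment.read_id,
        symbols=tuple(symbols),
        tracts=tuple(tracts),
        flagged_singletons=tuple(flagged),
    )


def summarize_population(
    classifications: Sequence[ReadClassification],
    panel: ParentalPanel,
    donor_fraction_threshold: float = 0.10,
) -> TractSummary:
    """Per-site parental tallies and the consensus exchange interval.

    The consensus interval is the longest run of sites whose donor fraction
    reaches the threshold (ties broken toward the leftmost run) — the
    population-level footprint of strand exchange.
    """
    if not classifications:
        raise ValueError("no read classifications to summarize")
    k = len(panel)
    recipient = [0] * k
    donor = [0] * k
    error = [0] * k
    missing = [0] * k
    flagged = [0] * k
    for cls in classifications:
        if len(cls.symbols) != k:
            raise ValueError("classification panel size mismatch")
        for i, sym in enumerate(cls.symbols):
            if sym == RECIPIENT:
                recipient[i] += 1
            elif sym == DONOR:
                donor[i] += 1
            elif sym == ERROR:
                error[i] += 1
            else:
                missing[i] += 1
        for i in cls.flagged_singletons:
            flagged[i] += 1

    donor_fraction = []
    error_fraction = []
    for i in range(k):
        covered = recipient[i] + donor[i] + error[i]
        donor_fraction.append(donor[i] / covered if covered else 0.0)
        error_fraction.append(error[i] / covered if covered else 0.0)

    best: Optional[tuple[int, int]] = None
    i = 0
    while i < k:
        if donor_fraction[i] < donor_fraction_threshold:
            i += 1
            continue
        j = i
        while j < k and donor_fraction[j] >= donor_fraction_threshold:
            j += 1
        if best is None or (j - i) > (best[1] - best[0] + 1):
            best = (i, j - 1)
        i = j
    return TractSummary(
        recipient=recipient,
        donor=donor,
        error=error,
        missing=missing,
        flagged_singleton=flagged,
        donor_fraction=donor_fraction,
        error_fraction=error_fraction,
        consensus_interval=best,
        n_reads=len(classifications),
    )
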