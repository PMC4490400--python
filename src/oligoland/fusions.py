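"""Read-support and blacklist filtering of chimeric-transcript candidates.

A candidate is retained iff

* spanning reads are strictly greater than the spanning threshold
  (default 2),
* total supporting reads are at least the total threshold (default 10),
* the gene pair is not on the normal-tissue blacklist.

Rejected candidates carry the first failing rule, in that order.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .model import FormatError, FusionCandidate


@dataclass
class FusionFilterConfig:
    min_spanning_exclusive: int = 2
    min_total_inclusive: int = 10
    blacklist: set[tuple[str, str]] = field(default_factory=set)
    ordered_blacklist: bool = False

    def __post_init__(self) -> None:
        if self.min_spanning_exclusive < 0 or self.min_total_inclusive < 0:
            raise ValueError("fusion thresholds must be non-negative")

    def is_blacklisted(self, gene5: str, gene3: str) -> bool:
        if (gene5, gene3) in self.blacklist:
            return True
        if not self.ordered_blacklist and (gene3, gene5) in self.blacklist:
            return True
        return False


def load_blacklist(
    path: str | Path, orientation: str = "unordered"
) -> set[tuple[str, str]]:
    """Load a gene-pair blacklist TSV (two symbols per line).

    Orientation semantics are applied at query time via
    ``FusionFilterConfig.ordered_blacklist``; this loader simply validates
    the file and returns the pair set as written.
    """
    if orientation not in ("ordered", "unordered"):
        raise ValueError(f"unknown orientation {orientation!r}")
    pairs: set[tuple[str, str]] = set()
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise FormatError(
                    f"{path}:{lineno}: blacklist line needs two gene symbols"
                )
            pairs.add((fields[0], fields[1]))
    return pairs


def filter_fusions(
    candidates: Sequence[FusionCandidate],
    cfg: FusionFilterConfig | None = None,
) -> tuple[list[FusionCandidate], pd.DataFrame]:
    """Apply the read-support and blacklist filters per candidate row.

    Returns the retained candidates and a reasons table with one row per
    input candidate (``reason`` is "retained" or the first failing rule:
    "spanning_reads", "total_supporting_reads" or "blacklist").
    """
    cfg = cfg or FusionFilterConfig()
    retained: list[FusionCandidate] = []
    rows = []
    for c in candidates:
        if c.spanning_reads <= cfg.min_spanning_exclusive:
            reason = "spanning_reads"
        elif c.total_supporting_reads < cfg.min_total_inclusive:
            reason = "total_supporting_reads"
        elif cfg.is_blacklisted(c.gene5, c.gene3):
            reason = "blacklist"
        else:
            reason = "retained"
            retained.append(c)
        rows.append(
            (
                c.sample_id,
                c.gene5,
                c.gene3,
                c.spanning_reads,
                c.total_supporting_reads,
                reason,
            )
        )
    reasons = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "gene5",
            "gene3",
            "spanning_reads",
            "total_supporting_reads",
            "reason",
        ],
    )
    return retained, reasons


def write_blacklist(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(pairs):
            fh.write(f"{a}\t{b}\n")
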