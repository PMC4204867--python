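"""Transcription coding and caregiver-response comparison statistics.

Caregiver responses are phonemically transcribed (SAMPA) within a CVC/CVV
frame; phonemes are consolidated into cross-language archiphoneme
categories (pipe-notated, e.g. |pb| covering /p b/) so that labeling can be
compared between caregivers and across languages.  Pairwise label
comparisons per utterance feed 'same' / 'different' incidence counts, and
differences between same-label proportions across dataset groups are tested
with a pooled two-proportion Z statistic at the 0.05 / 0.01 / 0.001 levels,
with normal-approximation confidence intervals for incidence bar graphs.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, FrozenSet, List, Optional, Tuple

import numpy as np
from scipy.stats import norm

SILENT_CODE = "#"
UNTRANSCRIBABLE_CODE = "xxx"
EMPTY_SLOT = ","
SLOTS = ("C1", "V1", "V2", "C2")

# two-sided normal critical values at the three significance levels
ALPHA_CRITICAL = {0.05: 1.95996, 0.01: 2.57583, 0.001: 3.29053}

LANGUAGES = ("English", "German", "French")


class AnalysisError(ValueError):
    pass


class CodingParseError(AnalysisError):
    pass


# ---------------------------------------------------------------------------
# transcription records
# ---------------------------------------------------------------------------

@dataclass
class TranscriptionRecord:
    token_id: str
    kind: str  # coded | silent | untranscribable
    slots: Dict[str, Optional[str]] = field(
        default_factory=lambda: {s: None for s in SLOTS}
    )


def parse_coding(raw: str, token_id: str = "") -> TranscriptionRecord:
    """Parse one raw transcription code.

    '#' marks a silent response and 'xxx' an untranscribable one (usually
    attempted mimicry).  Otherwise the code is a space-separated element
    list in a CVC or CVV frame with ',' marking empty slots; codes longer
    than three elements keep only their first three.
    """
    raw = raw.strip()
    if raw == SILENT_CODE:
        return TranscriptionRecord(token_id, "silent")
    if raw == UNTRANSCRIBABLE_CODE:
        return TranscriptionRecord(token_id, "untranscribable")
    if not raw:
        raise CodingParseError("empty code at position 0")
    elements = raw.split()
    if len(elements) > 3:
        elements = elements[:3]
    for pos, el in enumerate(elements):
        if any(ch.isspace() for ch in el):
            raise CodingParseError(f"malformed element {el!r} at position {pos}")
    rec = TranscriptionRecord(token_id, "coded")
    # CVC frame: C1 V1 C2 for 3 elements with final consonant; CVV when the
    # third element is vocalic.  With commas marking empty slots, position
    # semantics are explicit: element order is C1, V1, then V2-or-C2.
    padded = elements + [EMPTY_SLOT] * (3 - len(elements))
    c1, v1, third = padded
    rec.slots["C1"] = None if c1 == EMPTY_SLOT else c1
    rec.slots["V1"] = None if v1 == EMPTY_SLOT else v1
    if third != EMPTY_SLOT:
        if _looks_vocalic(third):
            rec.slots["V2"] = third
        else:
            rec.slots["C2"] = third
    if all(v is None for v in rec.slots.values()):
        raise CodingParseError("coded record needs at least one V or C at position 0")
    return rec


_VOCALIC_STARTERS = set("aeiouyAEIOUYQV{@23&69")


def _looks_vocalic(sampa: str) -> bool:
    head = sampa[0]
    if head in "jrl" and len(sampa) > 1:
        # onset-fused vowel variants (e.g. 'ja', 'rI') are vocalic elements
        return sampa[1] in _VOCALIC_STARTERS or sampa[1] in "jrl"
    return head in _VOCALIC_STARTERS


# ---------------------------------------------------------------------------
# archiphoneme tables
# ---------------------------------------------------------------------------

@dataclass
class ArchiphonemeTable:
    language: str
    mapping: Dict[str, str]

    def __post_init__(self) -> None:
        if self.language not in LANGUAGES:
            raise AnalysisError(f"unknown language {self.language!r}")


def load_archiphoneme_table(language: str) -> ArchiphonemeTable:
    """Load the shipped consolidation table for a language."""
    if language not in LANGUAGES:
        raise AnalysisError(f"unknown language {language!r}")
    path = resources.files("vocalearn.data") / f"archiphonemes_{language.lower()}.csv"
    mapping: Dict[str, str] = {}
    with path.open("r") as fh:
        for row in csv.DictReader(fh):
            phoneme = row["phoneme"]
            if phoneme in mapping:
                raise AnalysisError(
                    f"phoneme {phoneme!r} mapped twice in {language}"
                )
            mapping[phoneme] = row["archiphoneme"]
    return ArchiphonemeTable(language, mapping)


def consolidate(record: TranscriptionRecord,
                table: ArchiphonemeTable) -> Dict[str, str]:
    """Map each slot's phoneme to its archiphoneme; empty slots become '#'."""
    out: Dict[str, str] = {}
    for slot in SLOTS:
        phoneme = record.slots.get(slot)
        if phoneme is None:
            out[slot] = "#"
            continue
        if phoneme not in table.mapping:
            raise AnalysisError(
                f"phoneme {phoneme!r} not in the {table.language} table"
            )
        out[slot] = table.mapping[phoneme]
    return out


# ---------------------------------------------------------------------------
# dataset comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """'Same' / 'different' archiphoneme incidence between two labelings."""

    same_counts: Dict[str, int] = field(default_factory=dict)
    diff_counts: Dict[FrozenSet[str], int] = field(default_factory=dict)
    skipped: int = 0

    @property
    def total_same(self) -> int:
        return sum(self.same_counts.values())

    @property
    def total_different(self) -> int:
        return sum(self.diff_counts.values())

    @property
    def total_compared(self) -> int:
        return self.total_same + self.total_different


def compare_datasets(a: Dict[str, str], b: Dict[str, str]) -> ComparisonResult:
    """Pairwise per-token label comparison between two datasets.

    Each dataset maps token id -> archiphoneme label for one slot (C1 or
    V1).  Tokens labeled in both datasets increment a same-label counter
    (per archiphoneme) or a different-label counter (per unordered pair);
    tokens missing a label on either side are tallied as skipped.
    """
    ids_a, ids_b = set(a), set(b)
    if not ids_a & ids_b:
        raise AnalysisError("datasets share no token ids")
    result = ComparisonResult()
    for tid in ids_a | ids_b:
        la, lb = a.get(tid), b.get(tid)
        if la is None or lb is None:
            result.skipped += 1
            continue
        if la == lb:
            result.same_counts[la] = result.same_counts.get(la, 0) + 1
        else:
            key = frozenset((la, lb))
            result.diff_counts[key] = result.diff_counts.get(key, 0) + 1
    return result


def sum_group_comparisons(results: List[ComparisonResult]) -> ComparisonResult:
    """Element-wise sum of comparison counts over multiple dataset pairs."""
    total = ComparisonResult()
    for r in results:
        for k, v in r.same_counts.items():
            total.same_counts[k] = total.same_counts.get(k, 0) + v
        for k, v in r.diff_counts.items():
            total.diff_counts[k] = total.diff_counts.get(k, 0) + v
        total.skipped += r.skipped
    return total


# ---------------------------------------------------------------------------
# proportion statistics
# ---------------------------------------------------------------------------

@dataclass
class ProportionTest:
    x1: int
    n1: int
    x2: int
    n2: int
    p_hat1: float
    p_hat2: float
    p_pooled: float
    z: float
    significant_at: Tuple[float, ...]


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int) -> ProportionTest:
    """Pooled two-proportion Z-test with a two-sided decision rule.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with pooled p; the
    significance set holds every level in {0.05, 0.01, 0.001} whose
    two-sided critical value |z| exceeds.  Warns when the large-sample
    condition (pooled expected successes and failures >= 5 in each group)
    does not hold.
    """
    if n1 <= 0 or n2 <= 0:
        raise AnalysisError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise AnalysisError("counts must satisfy 0 <= x <= n")
    p1 = x1 / n1
    p2 = x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    for n in (n1, n2):
        if n * pooled < 5 or n * (1 - pooled) < 5:
            warnings.warn(
                "large-sample condition (n*p >= 5 and n*(1-p) >= 5) not met",
                stacklevel=2,
            )
            break
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = 0.0 if se == 0 else float((p1 - p2) / se)
    significant = tuple(
        alpha for alpha, crit in sorted(ALPHA_CRITICAL.items(), reverse=True)
        if abs(z) > crit
    )
    return ProportionTest(x1, n1, x2, n2, p1, p2, pooled, z, significant)


def proportion_ci(x: int, n: int, level: float = 0.95) -> Tuple[float, float]:
    """Normal-approximation CI for a proportion, truncated to [0, 1]."""
    if n <= 0:
        raise AnalysisError("n must be positive")
    if not 0 <= x <= n:
        raise AnalysisError("need 0 <= x <= n")
    p = x / n
    zcrit = float(norm.ppf(0.5 + level / 2.0))
    half = zcrit * np.sqrt(p * (1 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_transcription_csv(path) -> List[TranscriptionRecord]:
    """Read token_id,raw_code rows into parsed records."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(parse_coding(row["raw_code"], row["token_id"]))
    return out


def comparison_to_rows(result: ComparisonResult) -> List[Tuple[str, str, int]]:
    """Flatten a comparison into (kind, key, count) rows for CSV export."""
    rows: List[Tuple[str, str, int]] = []
    for label, count in sorted(result.same_counts.items()):
        rows.append(("same", label, count))
    for pair, count in sorted(result.diff_counts.items(), key=lambda t: sorted(t[0])):
        rows.append(("different", "/".join(sorted(pair)), count))
    rows.append(("skipped", "", result.skipped))
    return rows
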