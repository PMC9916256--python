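"""Lexicon-based interaction-severity grading.

A polarity lexicon (token -> score in [-1, 1], SentiWordNet-style) scores
an interaction sentence by the mean polarity of its matched tokens.
Strongly negative sentences describe dangerous interactions (high
severity); strongly positive ones advantageous interactions (low
severity); everything between is moderate/neutral. The cut points default
to the symmetric thirds (-1/3, +1/3) and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "PolarityLexicon",
    "SeverityResult",
    "load_lexicon",
    "polarity_score",
    "severity_class",
    "grade_sentence",
    "demo_lexicon",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (-1.0 / 3.0, 1.0 / 3.0)


@dataclass(frozen=True)
class PolarityLexicon:
    """Token -> polarity score map; scores in [-1, 1], tokens lower-case."""

    entries: dict[str, float]

    def __post_init__(self) -> None:
        for tok, score in self.entries.items():
            if tok != tok.lower():
                raise ValueError(f"lexicon token {tok!r} must be lower-case")
            if not -1.0 <= score <= 1.0:
                raise ValueError(f"score {score} for {tok!r} outside [-1, 1]")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class SeverityResult:
    """Polarity with its severity grade and interaction direction."""

    polarity: float
    level: str       # low | moderate | high
    direction: str   # advantageous | neutral | dangerous
    n_matched: int


def load_lexicon(path: str | Path) -> PolarityLexicon:
    """Load a token<TAB>score TSV; rejects duplicates and out-of-range scores."""
    entries: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected token<TAB>score, got {line!r}")
            token = parts[0].lower()
            try:
                score = float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric score {parts[1]!r}") from exc
            if not -1.0 <= score <= 1.0:
                raise ValueError(f"{path}:{lineno}: score {score} outside [-1, 1]")
            if token in entries:
                raise ValueError(f"{path}:{lineno}: duplicate token {token!r}")
            entries[token] = score
    return PolarityLexicon(entries)


def polarity_score(tokens, lexicon: PolarityLexicon) -> tuple[float, int]:
    """Mean polarity of the lexicon-matched tokens; (0.0, 0) when none match."""
    hits = [lexicon.entries[t] for t in tokens if t in lexicon.entries]
    if not hits:
        return 0.0, 0
    return sum(hits) / len(hits), len(hits)


def severity_class(score: float, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
                   n_matched: int = 0) -> SeverityResult:
    """Map a polarity score to a severity grade.

    score < t_low: high severity, dangerous; score > t_high: low severity,
    advantageous; otherwise moderate, neutral.
    """
    t_low, t_high = thresholds
    if not -1.0 <= t_low < t_high <= 1.0:
        raise ValueError(f"thresholds must satisfy -1 <= t_low < t_high <= 1, got {thresholds}")
    if score < t_low:
        level, direction = "high", "dangerous"
    elif score > t_high:
        level, direction = "low", "advantageous"
    else:
        level, direction = "moderate", "neutral"
    return SeverityResult(score, level, direction, n_matched)


def demo_lexicon() -> PolarityLexicon:
    """The small synthetic demonstration lexicon bundled with the package."""
    from importlib.resources import files

    return load_lexicon(str(files("ssoddi").joinpath("data/lexicon_demo.tsv")))


def grade_sentence(tokens, lexicon: PolarityLexicon,
                   thresholds: tuple[float, float] = DEFAULT_THRESHOLDS) -> SeverityResult:
    """Score a tokenized sentence and grade its interaction severity."""
    score, n = polarity_score([t.lower() for t in tokens], lexicon)
    return severity_class(score, thresholds, n_matched=n)
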