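"""Lexicon sentiment scoring with two pluggable scorers.

Comment valence is estimated twice -- by a rule-based scorer with
negation/booster handling (scorer A, scores in [-1, 1]) and by a
positive/negative word-list tone scorer (scorer B, scores in [-100, 100]) --
and the two are combined into a single *compound* score by z-standardizing
each over the analyzed corpus and averaging.  Averaging standardized scorers
improves reliability and downweights texts where the two methods diverge.

Both scorers are pluggable: any :class:`ValenceLexicon` loaded from a
two-column token/valence text file can stand behind either role.  The
bundled word lists are compact open lists written for this package; scorer B
deliberately does not claim equivalence with any proprietary dictionary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "ValenceLexicon",
    "SentimentScores",
    "tokenize",
    "lexicon_score",
    "tone_score",
    "health_word_pct",
    "compound_score",
    "scorer_agreement",
    "score_texts",
    "default_valence_lexicon",
    "default_tone_lexicon",
    "default_health_lexicon",
]

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_NONWORD_RE = re.compile(r"[^a-z0-9'\s]")

# rule constants for scorer A: negation flips and damps by N_FACTOR; booster
# increments push the following valenced token away from zero
N_FACTOR = -0.74
NORM_ALPHA = 15.0
NEGATION_SCOPE = 3


@dataclass
class ValenceLexicon:
    """Token -> valence mapping plus booster increments and negation tokens."""

    entries: dict[str, float]
    boosters: dict[str, float] = field(default_factory=dict)
    negators: set[str] = field(default_factory=set)
    name: str = "lexicon"

    def __post_init__(self):
        if not self.entries:
            raise ValueError("empty lexicon")
        for tok, v in self.entries.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite valence for {tok!r}")
        overlap = set(self.entries) & self.negators
        if overlap:
            raise ValueError(f"tokens in both entries and negators: {overlap}")

    @classmethod
    def from_files(
        cls,
        entries_path: str | Path,
        boosters_path: str | Path | None = None,
        negators_path: str | Path | None = None,
        name: str = "lexicon",
    ) -> "ValenceLexicon":
        entries = _read_tsv(entries_path)
        boosters = _read_tsv(boosters_path) if boosters_path else {}
        negators = set(_read_tokens(negators_path)) if negators_path else set()
        return cls(entries=entries, boosters=boosters, negators=negators, name=name)


def _read_tsv(path) -> dict[str, float]:
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tok, val = line.split("\t")
        out[tok] = float(val)
    return out


def _read_tokens(path) -> list[str]:
    return [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]


def _lexicon_dir() -> Path:
    return Path(resources.files("affsync") / "lexicons")


def default_valence_lexicon() -> ValenceLexicon:
    d = _lexicon_dir()
    return ValenceLexicon.from_files(
        d / "valence.tsv", d / "boosters.tsv", d / "negators.tsv", name="rule-valence"
    )


def default_tone_lexicon() -> ValenceLexicon:
    return ValenceLexicon.from_files(_lexicon_dir() / "tone.tsv", name="tone")


def default_health_lexicon() -> set[str]:
    return set(_read_tokens(_lexicon_dir() / "health.tsv"))


def tokenize(text: str) -> list[str]:
    """Lowercased whitespace tokens after URL and symbol/emoji stripping.

    This is also the tokenizer behind the minimum-word-count eligibility
    rule, which exists because single-token posts (a bare link or emoji)
    cannot be scored reliably.
    """
    text = _URL_RE.sub(" ", text.lower())
    text = _NONWORD_RE.sub(" ", text)
    return [t.strip("'") for t in text.split() if t.strip("'")]


def lexicon_score(text: str, lexicon: ValenceLexicon) -> float:
    """Rule-based valence of a text in [-1, 1] (scorer A).

    Sums the valences of matched tokens, flipping and damping a valence when
    a negator occurs within the preceding three tokens and adding booster
    increments toward the token's sign; the total is compressed into [-1, 1]
    by ``total / sqrt(total**2 + alpha)``.  A text with no lexicon matches
    scores exactly 0.
    """
    tokens = tokenize(text)
    if not tokens:
        raise ValueError("empty token stream; filter such texts upstream")
    total = 0.0
    for i, tok in enumerate(tokens):
        if tok not in lexicon.entries:
            continue
        val = lexicon.entries[tok]
        window = tokens[max(0, i - NEGATION_SCOPE) : i]
        for prev in window:
            if prev in lexicon.boosters:
                inc = lexicon.boosters[prev]
                val += inc if val > 0 else -inc
        if any(prev in lexicon.negators for prev in window):
            val *= N_FACTOR
        total += val
    if total == 0.0:
        return 0.0
    return float(total / np.sqrt(total**2 + NORM_ALPHA))


def tone_score(text: str, lexicon: ValenceLexicon) -> float:
    """Word-list tone in [-100, 100] (scorer B):
    100 * (pos - neg) / (pos + neg + 1)."""
    tokens = tokenize(text)
    if not tokens:
        raise ValueError("empty token stream; filter such texts upstream")
    pos = sum(1 for t in tokens if lexicon.entries.get(t, 0) > 0)
    neg = sum(1 for t in tokens if lexicon.entries.get(t, 0) < 0)
    return 100.0 * (pos - neg) / (pos + neg + 1.0)


def health_word_pct(text: str, health_lexicon: set[str]) -> float:
    """Percentage of tokens found in the health word list, in [0, 100]."""
    tokens = tokenize(text)
    if not tokens:
        raise ValueError("zero tokens")
    matched = sum(1 for t in tokens if t in health_lexicon)
    return 100.0 * matched / len(tokens)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("constant input vector (zero variance)")
    return (x - x.mean()) / sd


def compound_score(raw_a: np.ndarray, raw_b: np.ndarray) -> np.ndarray:
    """Elementwise mean of the z-scored scorer outputs.

    The standardization population is the full vector supplied -- in the
    pipeline, every retained comment of every analyzed user -- so per-user
    trajectories stay on a common scale.  Invariant to affine rescaling of
    either raw input.
    """
    a = np.asarray(raw_a, float)
    b = np.asarray(raw_b, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need equal-length vectors of length >= 2")
    return (_zscore(a) + _zscore(b)) / 2.0


def scorer_agreement(raw_a: np.ndarray, raw_b: np.ndarray) -> tuple[float, float]:
    """(Cronbach's alpha, Pearson r) for the two-scorer scale.

    Alpha is computed on the z-scored vectors as a two-item scale,
    ``k/(k-1) * (1 - sum(var_i)/var(total))``; for standardized items this
    equals ``2 r / (1 + r)``.
    """
    a = np.asarray(raw_a, float)
    b = np.asarray(raw_b, float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    za, zb = _zscore(a), _zscore(b)
    r = float(np.corrcoef(za, zb)[0, 1])
    total_var = np.var(za + zb, ddof=1)
    item_var = np.var(za, ddof=1) + np.var(zb, ddof=1)
    alpha = 2.0 * (1.0 - item_var / total_var)
    return float(alpha), r


@dataclass
class SentimentScores:
    """Aligned per-comment scores and covariates for one set of texts."""

    raw_a: np.ndarray
    raw_b: np.ndarray
    compound: np.ndarray
    word_count: np.ndarray
    health_pct: np.ndarray


def score_texts(
    texts: list[str],
    valence_lexicon: ValenceLexicon | None = None,
    tone_lexicon: ValenceLexicon | None = None,
    health_lexicon: set[str] | None = None,
) -> SentimentScores:
    """Score a corpus of texts with both scorers and compute covariates.

    The compound score is standardized over exactly the texts supplied, so
    callers should pass the full analyzed corpus in one call.
    """
    if valence_lexicon is None:
        valence_lexicon = default_valence_lexicon()
    if tone_lexicon is None:
        tone_lexicon = default_tone_lexicon()
    if health_lexicon is None:
        health_lexicon = default_health_lexicon()
    raw_a = np.array([lexicon_score(t, valence_lexicon) for t in texts])
    raw_b = np.array([tone_score(t, tone_lexicon) for t in texts])
    wc = np.array([len(tokenize(t)) for t in texts], dtype=float)
    hp = np.array([health_word_pct(t, health_lexicon) for t in texts])
    return SentimentScores(
        raw_a=raw_a,
        raw_b=raw_b,
        compound=compound_score(raw_a, raw_b),
        word_count=wc,
        health_pct=hp,
    )
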