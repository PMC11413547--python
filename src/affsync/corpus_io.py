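"""Ingestion and eligibility filtering of community interaction records.

An *interaction* pairs one user comment with the text of the parent post or
comment it replied to.  Records arrive as JSON-Lines (one record per line,
UTF-8); they are grouped per user, sorted chronologically, and passed through
the study's exclusion rules:

* comments flagged as removed (moderation or self-deletion), or whose text
  matches a configurable deletion sentinel, are excluded,
* comments with fewer than three words (after URL/emoji stripping) are
  excluded, because single-token posts cannot be scored reliably,
* users remain eligible only with at least 100 interactions after these
  exclusions -- the activity floor required for wavelet estimates at the
  lowest frequencies -- and must not be on an explicit exclusion list
  (moderators, bot accounts).

Every excluded record carries exactly one reason code, and retained plus
excluded counts always reconcile with the input count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .sentiment import tokenize

__all__ = [
    "InteractionRecord",
    "UserHistory",
    "PairedSeries",
    "read_interactions",
    "filter_comments",
    "select_eligible_users",
    "to_paired_series",
    "retention_percentage",
    "exclusion_table",
    "DEFAULT_DELETION_SENTINELS",
]

DEFAULT_DELETION_SENTINELS = ("[removed]", "[deleted]")

REASON_REMOVED = "removed"
REASON_TOO_SHORT = "too_short"
REASON_MISSING = "missing"


@dataclass
class InteractionRecord:
    user_id: str
    timestamp: float
    comment_text: str
    parent_text: str
    score: int = 0
    removed_flag: bool = False

    def __post_init__(self):
        if not self.user_id:
            raise ValueError("empty user_id")
        if not np.isfinite(self.timestamp):
            raise ValueError("non-finite timestamp")


@dataclass
class UserHistory:
    """Chronologically sorted records for one user plus an exclusion log of
    (record, reason-code) pairs."""

    user_id: str
    records: list[InteractionRecord] = field(default_factory=list)
    exclusion_log: list[tuple[InteractionRecord, str]] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return len(self.records)

    @property
    def n_excluded(self) -> int:
        return len(self.exclusion_log)


@dataclass
class PairedSeries:
    """Per-user paired sentiment vectors plus covariates, all chronological."""

    user_id: str
    self_sentiment: np.ndarray
    peer_sentiment: np.ndarray
    word_count: np.ndarray
    health_pct: np.ndarray
    timestamps: np.ndarray

    def __post_init__(self):
        n = len(self.self_sentiment)
        for name in ("peer_sentiment", "word_count", "health_pct", "timestamps"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")

    @property
    def n(self) -> int:
        return len(self.self_sentiment)

    @property
    def days_active_span(self) -> float:
        """Tenure as the span last-first post, in days."""
        if self.n < 2:
            return 0.0
        return float((self.timestamps.max() - self.timestamps.min()) / 86400.0)

    @property
    def days_active_distinct(self) -> int:
        """Number of distinct UTC days with at least one comment."""
        return len(np.unique(np.floor(self.timestamps / 86400.0)))


_REQUIRED = ("user_id", "timestamp", "comment_text", "parent_text")


def read_interactions(
    source: str | Path | Iterable[str],
    max_malformed_fraction: float = 0.5,
) -> dict[str, UserHistory]:
    """Parse a JSON-Lines stream into per-user chronological histories.

    Unknown fields are ignored; malformed lines are counted and skipped, but
    if they exceed ``max_malformed_fraction`` of the stream a ValueError is
    raised.  Returns user_id -> :class:`UserHistory` with records sorted by
    timestamp (stable for ties).
    """
    if isinstance(source, (str, Path)):
        lines = Path(source).read_text(encoding="utf-8").splitlines()
    else:
        lines = list(source)
    histories: dict[str, UserHistory] = {}
    n_bad = 0
    n_total = 0
    for line in lines:
        if not line.strip():
            continue
        n_total += 1
        try:
            obj = json.loads(line)
            if not all(k in obj for k in _REQUIRED):
                raise KeyError("missing required field")
            rec = InteractionRecord(
                user_id=str(obj["user_id"]),
                timestamp=float(obj["timestamp"]),
                comment_text="" if obj["comment_text"] is None else str(obj["comment_text"]),
                parent_text="" if obj["parent_text"] is None else str(obj["parent_text"]),
                score=int(obj.get("score", 0)),
                removed_flag=bool(obj.get("removed_flag", False)),
            )
        except (json.JSONDecodeError, KeyError, TypeError, ValueError):
            n_bad += 1
            continue
        histories.setdefault(rec.user_id, UserHistory(rec.user_id)).records.append(rec)
    if n_total and n_bad / n_total > max_malformed_fraction:
        raise ValueError(f"{n_bad}/{n_total} malformed lines")
    for h in histories.values():
        h.records.sort(key=lambda r: r.timestamp)
    return histories


def filter_comments(
    history: UserHistory,
    min_words: int = 3,
    deletion_sentinels: tuple[str, ...] = DEFAULT_DELETION_SENTINELS,
) -> UserHistory:
    """Apply the removed/missing/word-count exclusions to one history.

    Records flagged removed (or whose text equals a deletion sentinel) get
    reason ``removed``; records with missing/empty text get ``missing``;
    records with fewer than ``min_words`` whitespace tokens after URL/emoji
    stripping get ``too_short``.  Order is preserved and the operation is
    idempotent.
    """
    kept: list[InteractionRecord] = []
    log = list(history.exclusion_log)
    for rec in history.records:
        text = rec.comment_text
        if rec.removed_flag or text.strip() in deletion_sentinels:
            log.append((rec, REASON_REMOVED))
        elif not text.strip():
            log.append((rec, REASON_MISSING))
        elif len(tokenize(text)) < min_words:
            log.append((rec, REASON_TOO_SHORT))
        else:
            kept.append(rec)
    return UserHistory(user_id=history.user_id, records=kept, exclusion_log=log)


def select_eligible_users(
    corpus: dict[str, UserHistory],
    min_activity: int = 100,
    exclude_ids: set[str] | None = None,
) -> list[str]:
    """User ids with post-exclusion activity >= ``min_activity``, minus any
    explicitly excluded ids (moderators, bots), in sorted deterministic
    order."""
    exclude_ids = exclude_ids or set()
    return sorted(
        uid
        for uid, h in corpus.items()
        if uid not in exclude_ids and h.n_retained >= min_activity
    )


def to_paired_series(
    history: UserHistory,
    sentiment_fn: Callable[[str], float],
    health_lexicon: set[str] | None = None,
    min_length: int = 100,
) -> PairedSeries:
    """Build the paired self/peer sentiment vectors for one filtered history.

    ``sentiment_fn`` maps a text to a real score (in the pipeline this is a
    closure over corpus-level compound standardization).  Raises ValueError
    if the filtered history is shorter than ``min_length`` -- callers drop
    the user and log the reason rather than analyzing an unreliable series.
    """
    if history.n_retained < min_length:
        raise ValueError(
            f"user {history.user_id}: {history.n_retained} records "
            f"< minimum series length {min_length}"
        )
    if health_lexicon is None:
        from .sentiment import default_health_lexicon

        health_lexicon = default_health_lexicon()
    from .sentiment import health_word_pct

    self_s, peer_s, wc, hp, ts = [], [], [], [], []
    for rec in history.records:
        self_s.append(sentiment_fn(rec.comment_text))
        peer_s.append(sentiment_fn(rec.parent_text) if rec.parent_text.strip() else 0.0)
        toks = tokenize(rec.comment_text)
        wc.append(len(toks))
        hp.append(health_word_pct(rec.comment_text, health_lexicon) if toks else 0.0)
        ts.append(rec.timestamp)
    return PairedSeries(
        user_id=history.user_id,
        self_sentiment=np.asarray(self_s, float),
        peer_sentiment=np.asarray(peer_s, float),
        word_count=np.asarray(wc, float),
        health_pct=np.asarray(hp, float),
        timestamps=np.asarray(ts, float),
    )


def retention_percentage(n_total: int, n_excluded: int) -> float:
    """Percentage of interactions retained after exclusions:
    100 * (total - excluded) / total."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_excluded <= n_total:
        raise ValueError("n_excluded out of range")
    return 100.0 * (n_total - n_excluded) / n_total


def exclusion_table(corpus: dict[str, UserHistory]) -> pd.DataFrame:
    """Tabular (CSV-ready) exclusion log across a corpus: one row per
    excluded record with user id, timestamp and reason code."""
    rows = [
        {"user_id": uid, "timestamp": rec.timestamp, "reason": reason}
        for uid, h in corpus.items()
        for rec, reason in h.exclusion_log
    ]
    return pd.DataFrame(rows, columns=["user_id", "timestamp", "reason"])
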