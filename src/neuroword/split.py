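"""Deterministic, leakage-safe sentence-level train/val/test splitting.

The same sentence shown to different subjects must land in the same split,
so the split is a pure function of the normalized sentence text: a SHA-1
digest mapped to [0, 1) and thresholded at the cumulative ratios.  Adding
new sentences never moves existing ones.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .containers import EpochSet

SPLITS = ("train", "val", "test")
_WS = re.compile(r"\s+")


def normalize_sentence(text: str) -> str:
    """Lowercase and collapse whitespace: the hashing key."""
    return _WS.sub(" ", text.strip().lower())


def sentence_unit(text: str) -> float:
    """Map a normalized sentence to a uniform value in [0, 1).

    First 8 bytes of SHA-1 as an unsigned integer over 2^64 — stable across
    platforms and Python processes (unlike builtin ``hash``).
    """
    digest = hashlib.sha1(normalize_sentence(text).encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") / 2.0**64


@dataclass
class SplitAssignment:
    """Mapping sentence text -> split label, keyed by normalized text."""

    assignment: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, text: str) -> str:
        return self.assignment[normalize_sentence(text)]

    def __contains__(self, text: str) -> bool:
        return normalize_sentence(text) in self.assignment

    def __len__(self) -> int:
        return len(self.assignment)

    def counts(self) -> dict[str, int]:
        c = {s: 0 for s in SPLITS}
        for v in self.assignment.values():
            c[v] += 1
        return c

    def save(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.assignment.items()), columns=["sentence_key", "split"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "SplitAssignment":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["sentence_key"], df["split"])))


def split_sentences(
    corpus_sentences: list[str],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> SplitAssignment:
    """Assign each sentence to train/val/test by thresholding its digest.

    Ratios must be non-negative and sum to 1.  Achieved fractions are
    binomial around the ratios, not exact quotas.
    """
    if any(r < 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must be non-negative and sum to 1")
    t_train = ratios[0]
    t_val = ratios[0] + ratios[1]
    out: dict[str, str] = {}
    for text in corpus_sentences:
        key = normalize_sentence(text)
        u = sentence_unit(key)
        out[key] = "train" if u < t_train else ("val" if u < t_val else "test")
    return SplitAssignment(out)


def check_leakage(split, epochs: EpochSet,
                  sentence_texts: dict | None = None) -> dict:
    """Count epochs per split and verify zero cross-split sentence overlap.

    ``split`` is a :class:`SplitAssignment` or a manifest DataFrame with
    columns ``sentence_key``/``split`` (a manifest may be corrupt, i.e. list
    one key under several splits — that is what the overlap count detects).
    ``epochs.sentence_ids`` may hold raw sentence texts or opaque ids; in the
    latter case pass ``sentence_texts`` mapping id -> text.  Raises on any
    sentence without an assignment.
    """
    if isinstance(split, pd.DataFrame):
        labels_by_key: dict[str, set[str]] = {}
        for key, label in zip(split["sentence_key"], split["split"]):
            labels_by_key.setdefault(normalize_sentence(str(key)), set()).add(label)
    else:
        labels_by_key = {k: {v} for k, v in split.assignment.items()}

    per_split = {s: 0 for s in SPLITS}
    used_keys: set[str] = set()
    for sid in epochs.sentence_ids:
        text = sentence_texts[sid] if sentence_texts is not None else sid
        key = normalize_sentence(str(text))
        if key not in labels_by_key:
            raise KeyError(f"sentence {sid!r} has no split assignment")
        used_keys.add(key)
        per_split[sorted(labels_by_key[key])[0]] += 1
    overlap = sum(1 for k in used_keys if len(labels_by_key[k]) > 1)
    return {"epochs_per_split": per_split,
            "n_sentences": len(used_keys),
            "cross_split_overlap": overlap}
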