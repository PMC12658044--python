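"""Synthetic M/EEG study generator with a planted embedding->sensor forward model.

Emulates the structure of word-level reading/listening experiments: a
Zipf-distributed lexicon with part-of-speech and orthographic attributes,
sentences presented at a fixed stimulus-onset asynchrony (RSVP-style,
one word every 300 ms by default), and per-subject recordings in which
every word evokes a response equal to a subject-specific linear mixture
of its embedding, convolved with a temporal kernel, plus sensor noise.

Because the response is linear in the word embedding, decodability is
provable in the noiseless limit, which gives the test suite sharp oracles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Recording, validate_events

logger = logging.getLogger(__name__)

POS_TAGS = ("NOUN", "VERB", "ADJ", "ADV", "FUNCTION")
# content-word proportions, roughly mirroring natural-language distributions
_CONTENT_POS = ("NOUN", "VERB", "ADJ", "ADV")
_CONTENT_POS_P = (0.45, 0.25, 0.18, 0.12)

_ALPHABET = np.array(list("abcdefghijklmnopqrstuvwxyz"))
# skewed first/last-letter distributions so orthographic chance baselines
# (same first/last letter) are non-degenerate
_EDGE_LETTER_P = np.array(
    [8, 2, 4, 3, 6, 3, 2, 5, 4, 1, 1, 3, 4, 5, 5, 3, 1, 5, 9, 9,
     2, 1, 4, 1, 2, 1], dtype=float)
_EDGE_LETTER_P /= _EDGE_LETTER_P.sum()


class InvalidConfigError(ValueError):
    """Raised when a synthetic study configuration violates its contract."""


class MissingWordError(KeyError):
    """Raised when a corpus word has no embedding."""


@dataclass
class SyntheticConfig:
    """Study-level knobs for the synthetic generator.

    ``snr`` is the ratio of evoked-response power to noise power; ``np.inf``
    yields noiseless recordings, 0 is rejected.  ``seed`` fully determines
    every output.
    """

    vocab_size: int = 250
    zipf_exponent: float = 1.0
    n_sentences: int = 200
    sentence_length_range: tuple[int, int] = (5, 12)
    n_subjects: int = 2
    n_sensors: int = 32
    sampling_rate_hz: float = 200.0
    embedding_dim: int = 64
    snr: float = 5.0
    response_latency_s: float = 0.1
    response_duration_s: float = 0.4
    soa_s: float = 0.3
    sentence_gap_s: float = 1.0
    noise_color: str = "white"  # "white" or "pink"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.vocab_size, self.n_sentences + 1, self.n_subjects,
               self.n_sensors, self.embedding_dim) < 1:
            raise InvalidConfigError("all counts must be >= 1")
        lo, hi = self.sentence_length_range
        if lo > hi or lo < 1:
            raise InvalidConfigError("sentence_length_range min must be in [1, max]")
        if not self.snr > 0:
            raise InvalidConfigError("snr must be > 0 (np.inf for noiseless)")
        if self.sampling_rate_hz <= 0 or self.response_duration_s <= 0:
            raise InvalidConfigError("rates and durations must be positive")
        if self.response_latency_s < 0:
            raise InvalidConfigError("response latency must be non-negative")
        if self.noise_color not in ("white", "pink"):
            raise InvalidConfigError("noise_color must be 'white' or 'pink'")

    def to_json(self) -> str:
        d = asdict(self)
        d["sentence_length_range"] = list(d["sentence_length_range"])
        return json.dumps(d, indent=2)

    @classmethod
    def from_mapping(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "sentence_length_range" in d:
            d["sentence_length_range"] = tuple(d["sentence_length_range"])
        return cls(**d)


@dataclass
class Lexicon:
    """Word inventory with Zipf mass, gold POS tags and orthographic length."""

    words: list[str]
    frequency_weight: np.ndarray
    pos_tag: list[str]
    length: np.ndarray

    def __post_init__(self) -> None:
        self.frequency_weight = np.asarray(self.frequency_weight, dtype=np.float64)
        self.length = np.asarray(self.length, dtype=int)
        if len(set(self.words)) != len(self.words):
            raise ValueError("lexicon words must be unique")
        if not np.isclose(self.frequency_weight.sum(), 1.0):
            raise ValueError("frequency weights must sum to 1")
        if any(t not in POS_TAGS for t in self.pos_tag):
            raise ValueError(f"pos tags must be in {POS_TAGS}")
        if not np.array_equal(self.length, [len(w) for w in self.words]):
            raise ValueError("length must equal character count")

    def pos_of(self) -> dict[str, str]:
        return dict(zip(self.words, self.pos_tag))

    def __len__(self) -> int:
        return len(self.words)


@dataclass
class SentenceCorpus:
    """Sentences with per-word onsets at a fixed stimulus-onset asynchrony."""

    sentences: list[list[str]]
    sentence_ids: list[str]
    word_onsets: list[np.ndarray]  # onsets in seconds, global timeline
    soa_s: float

    def __post_init__(self) -> None:
        if not (len(self.sentences) == len(self.sentence_ids) == len(self.word_onsets)):
            raise ValueError("corpus field lengths disagree")

    @property
    def n_words(self) -> int:
        return sum(len(s) for s in self.sentences)

    def texts(self) -> list[str]:
        return [" ".join(s) for s in self.sentences]

    def unique_words(self) -> list[str]:
        return sorted({w for s in self.sentences for w in s})


@dataclass
class ForwardModel:
    """Planted linear generative model mapping embeddings to sensor space.

    ``mixing[s]`` is the (n_sensors x d) map of subject ``s``; ``kernel`` is
    the evoked temporal waveform sampled at the recording rate with support
    inside [latency, latency + duration].
    """

    mixing: np.ndarray  # (n_subjects, n_sensors, d)
    kernel: np.ndarray  # (n_kernel_samples,)
    kernel_offset_samples: int
    sensor_positions: np.ndarray  # (n_sensors, 2)
    sampling_rate_hz: float

    @property
    def kernel_peak_lag_s(self) -> float:
        """Lag of the kernel maximum relative to word onset, in seconds."""
        peak = self.kernel_offset_samples + int(np.argmax(self.kernel))
        return peak / self.sampling_rate_hz


def _word_form(rng: np.random.Generator, length: int) -> str:
    first, last = rng.choice(_ALPHABET, size=2, p=_EDGE_LETTER_P)
    middle = rng.choice(_ALPHABET, size=max(0, length - 2))
    return first + "".join(middle) + (last if length > 1 else "")


def make_lexicon(config: SyntheticConfig) -> Lexicon:
    """Build a Zipf-weighted lexicon with POS tags and controlled word forms.

    Weights follow w_r proportional to r^(-zipf_exponent) over rank r.
    FUNCTION tags are concentrated on the highest-frequency ranks (the top
    15% of probability mass), mimicking natural language; remaining words
    get content-word tags.  Word lengths are drawn in [2, 12] letters with
    skewed first/last letter distributions.
    """
    if config.vocab_size < 20:
        raise InvalidConfigError("vocab_size must be >= 20")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x1e5]))
    ranks = np.arange(1, config.vocab_size + 1, dtype=np.float64)
    weights = ranks ** (-config.zipf_exponent)
    weights /= weights.sum()

    words: list[str] = []
    seen: set[str] = set()
    while len(words) < config.vocab_size:
        length = int(rng.integers(2, 13))
        w = _word_form(rng, length)
        if w not in seen:
            seen.add(w)
            words.append(w)

    cum = np.cumsum(weights)
    pos = []
    for r in range(config.vocab_size):
        if cum[r] <= 0.15 or (r == 0 and weights[0] > 0.15):
            pos.append("FUNCTION")
        else:
            pos.append(rng.choice(_CONTENT_POS, p=_CONTENT_POS_P))
    return Lexicon(words=words, frequency_weight=weights, pos_tag=pos,
                   length=np.array([len(w) for w in words]))


def make_corpus(lexicon: Lexicon, config: SyntheticConfig) -> SentenceCorpus:
    """Sample sentences i.i.d. from the lexicon's Zipf weights.

    Words within a sentence start every ``soa_s`` seconds; sentences are laid
    out sequentially on one global timeline separated by ``sentence_gap_s``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xc0]))
    lo, hi = config.sentence_length_range
    sentences: list[list[str]] = []
    onsets: list[np.ndarray] = []
    ids: list[str] = []
    t = config.sentence_gap_s
    words_arr = np.array(lexicon.words)
    for s in range(config.n_sentences):
        n = int(rng.integers(lo, hi + 1))
        sent = list(rng.choice(words_arr, size=n, p=lexicon.frequency_weight))
        sentences.append([str(w) for w in sent])
        onsets.append(t + config.soa_s * np.arange(n))
        ids.append(f"s{s:05d}")
        t = onsets[-1][-1] + config.soa_s + config.sentence_gap_s
    return SentenceCorpus(sentences=sentences, sentence_ids=ids,
                          word_onsets=onsets, soa_s=config.soa_s)


def make_forward_model(config: SyntheticConfig) -> ForwardModel:
    """Draw per-subject mixing maps, a half-cosine response kernel and a layout.

    Mixing entries are i.i.d. N(0, 1/d) so each subject's map is a distinct,
    almost-surely full-rank linear code of the embedding; subjects share the
    sensor layout but not the mixing.
    """
    ss = np.random.SeedSequence([config.seed, 0xf0])
    rng_layout, rng_mix = [np.random.default_rng(s) for s in ss.spawn(2)]
    positions = rng_layout.uniform(0.0, 1.0, size=(config.n_sensors, 2))
    d = config.embedding_dim
    mixing = rng_mix.standard_normal(
        (config.n_subjects, config.n_sensors, d)) / np.sqrt(d)

    n_k = max(1, int(round(config.response_duration_s * config.sampling_rate_hz)))
    # half-cosine bump: zero at both ends, peak mid-response
    phase = (np.arange(n_k) + 0.5) / n_k
    kernel = np.sin(np.pi * phase)
    offset = int(round(config.response_latency_s * config.sampling_rate_hz))
    return ForwardModel(mixing=mixing, kernel=kernel,
                        kernel_offset_samples=offset,
                        sensor_positions=positions,
                        sampling_rate_hz=config.sampling_rate_hz)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Gaussian noise with a 1/f amplitude spectrum, unit variance."""
    n, c = shape
    spec = np.fft.rfft(rng.standard_normal((n, c)), axis=0)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1] if len(freqs) > 1 else 1.0
    spec /= np.sqrt(freqs)[:, None]
    x = np.fft.irfft(spec, n=n, axis=0)
    x /= x.std(axis=0, keepdims=True)
    return x


def simulate_recordings(
    corpus: SentenceCorpus,
    embeddings,
    forward_model: ForwardModel,
    config: SyntheticConfig,
) -> list[tuple[Recording, pd.DataFrame]]:
    """Render one recording and events table per subject.

    The clean signal is the superposition, over words, of
    ``mixing @ Y_word`` placed along the kernel at the word onset; white (or
    optionally pink) Gaussian noise is added with power ``response_power/snr``.
    All subjects see the same corpus; their event tables differ only in the
    subject column.
    """
    for w in corpus.unique_words():
        if w not in embeddings:
            raise MissingWordError(f"no embedding for corpus word {w!r}")

    fs = config.sampling_rate_hz
    last = max((o[-1] for o in corpus.word_onsets), default=0.0)
    n_samples = int(round((last + 3.5) * fs))
    ss = np.random.SeedSequence([config.seed, 0x51])
    noise_seeds = ss.spawn(config.n_subjects)

    # event table layout shared across subjects
    rows = []
    for sent, sid, ons in zip(corpus.sentences, corpus.sentence_ids,
                              corpus.word_onsets):
        for w, o in zip(sent, ons):
            rows.append((float(o), config.soa_s, w, sid))

    out: list[tuple[Recording, pd.DataFrame]] = []
    kernel, offset = forward_model.kernel, forward_model.kernel_offset_samples
    for s in range(config.n_subjects):
        subject = f"sub-{s + 1:02d}"
        clean = np.zeros((n_samples, config.n_sensors))
        mix = forward_model.mixing[s]
        for onset, _, word, _ in rows:
            topo = mix @ embeddings[word]  # (n_sensors,)
            i0 = int(round(onset * fs)) + offset
            i1 = min(i0 + len(kernel), n_samples)
            if i0 < n_samples:
                clean[i0:i1] += np.outer(kernel[: i1 - i0], topo)
        resp_power = float(np.mean(clean**2))
        if np.isinf(config.snr):
            signal = clean
        else:
            sigma = np.sqrt(resp_power / config.snr)
            rng = np.random.default_rng(noise_seeds[s])
            if config.noise_color == "pink":
                noise = _pink_noise(rng, clean.shape)
            else:
                noise = rng.standard_normal(clean.shape)
            signal = clean + sigma * noise
        rec = Recording(signal=signal, sampling_rate_hz=fs,
                        sensor_positions=forward_model.sensor_positions,
                        subject_id=subject)
        events = pd.DataFrame(rows, columns=["onset", "duration", "word",
                                             "sentence_id"])
        events["subject"] = subject
        out.append((rec, validate_events(events)))
    return out


def simulate_study(config: SyntheticConfig):
    """Convenience wrapper: lexicon -> corpus -> forward model -> recordings.

    Returns ``(lexicon, corpus, forward_model, [(Recording, events), ...])``
    using the deterministic fallback embedding backend at
    ``config.embedding_dim``.
    """
    from .embeddings import embed_words, FallbackBackend

    lexicon = make_lexicon(config)
    corpus = make_corpus(lexicon, config)
    fm = make_forward_model(config)
    table = embed_words(lexicon.words,
                        FallbackBackend(dim=config.embedding_dim,
                                        seed=config.seed))
    recordings = simulate_recordings(corpus, table, fm, config)
    return lexicon, corpus, fm, table, recordings


# -- on-disk format ----------------------------------------------------------

def save_recording(rec: Recording, events: pd.DataFrame, out_dir: str | Path) -> None:
    """Write the flat binary + JSON sidecar + events TSV layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = rec.subject_id
    rec.signal.astype(np.float32).tofile(out / f"{stem}_recording.bin")
    sidecar = {
        "sampling_rate_hz": rec.sampling_rate_hz,
        "n_sensors": rec.n_sensors,
        "n_samples": int(rec.signal.shape[0]),
        "sensor_positions": rec.sensor_positions.tolist(),
        "subject_id": rec.subject_id,
        "dtype": "float32",
    }
    (out / f"{stem}_recording.json").write_text(json.dumps(sidecar, indent=2))
    events.to_csv(out / f"{stem}_events.tsv", sep="\t", index=False)


def load_recording(out_dir: str | Path, subject_id: str) -> tuple[Recording, pd.DataFrame]:
    out = Path(out_dir)
    sidecar = json.loads((out / f"{subject_id}_recording.json").read_text())
    raw = np.fromfile(out / f"{subject_id}_recording.bin", dtype=np.float32)
    signal = raw.reshape(sidecar["n_samples"], sidecar["n_sensors"])
    rec = Recording(signal=signal.astype(np.float64),
                    sampling_rate_hz=sidecar["sampling_rate_hz"],
                    sensor_positions=np.array(sidecar["sensor_positions"]),
                    subject_id=sidecar["subject_id"])
    events = pd.read_csv(out / f"{subject_id}_events.tsv", sep="\t")
    return rec, validate_events(events)
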