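"""Audio and annotation I/O, and the shared time-interval data model.

Waveforms are mono float64 arrays in [-1, 1]; annotations are ordered,
non-overlapping labeled intervals, interchangeable with Praat TextGrid
interval tiers (long and short text formats, UTF-8 or UTF-16).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import scipy.io.wavfile

logger = logging.getLogger(__name__)

__all__ = [
    "Waveform",
    "Interval",
    "IntervalTier",
    "TextGridParseError",
    "read_wav",
    "write_wav",
    "read_textgrid",
    "write_textgrid",
]


class TextGridParseError(ValueError):
    """Raised when a TextGrid file cannot be parsed; names the offending line."""


@dataclass
class Waveform:
    """Sampled mono audio.

    samples are dimensionless amplitudes, nominally in [-1, 1]; rate is in Hz;
    start_time anchors the first sample on an absolute time axis (seconds).
    """

    samples: np.ndarray
    rate: float
    start_time: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Waveform samples must be one-dimensional (mono)")
        if not self.rate > 0:
            raise ValueError("Waveform rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Waveform samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.samples)) / self.rate

    def slice(self, start: float, end: float) -> "Waveform":
        """Sample-aligned sub-waveform covering [start, end) in absolute time."""
        i0 = max(0, int(round((start - self.start_time) * self.rate)))
        i1 = min(len(self.samples), int(round((end - self.start_time) * self.rate)))
        if i1 <= i0:
            raise ValueError(f"empty slice [{start}, {end})")
        return Waveform(self.samples[i0:i1], self.rate, self.start_time + i0 / self.rate)


@dataclass(frozen=True)
class Interval:
    start: float
    end: float
    label: str = ""

    def __post_init__(self):
        if not self.end > self.start:
            raise ValueError(f"Interval end ({self.end}) must exceed start ({self.start})")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end


@dataclass
class IntervalTier:
    """Ordered, non-overlapping labeled intervals (one Praat interval tier)."""

    name: str
    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self):
        for a, b in zip(self.intervals, self.intervals[1:]):
            if b.start < a.end - 1e-12:
                raise ValueError(
                    f"tier {self.name!r}: intervals [{a.start},{a.end}] and "
                    f"[{b.start},{b.end}] overlap or are out of order"
                )

    def __len__(self):
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def labeled(self) -> list[Interval]:
        """Intervals with a non-empty label (empty labels are non-units)."""
        return [iv for iv in self.intervals if iv.label.strip()]

    def boundaries(self, interior_only: bool = False) -> np.ndarray:
        """Sorted unique interval edge times; optionally drop the tier extremes."""
        edges = sorted({iv.start for iv in self.intervals} | {iv.end for iv in self.intervals})
        if interior_only and len(edges) >= 2:
            edges = edges[1:-1]
        return np.asarray(edges)


# ---------------------------------------------------------------------------
# WAV


def read_wav(path) -> Waveform:
    """Read a PCM/float WAV file; stereo is averaged to mono, samples scaled to [-1, 1]."""
    try:
        rate, data = scipy.io.wavfile.read(path)
    except ValueError as exc:
        raise ValueError(f"unreadable WAV file {path}: {exc}") from exc
    if data.ndim == 2:
        data = data.astype(np.float64).mean(axis=1)
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:  # float32/float64, or already-averaged stereo
        samples = np.asarray(data, dtype=np.float64)
    return Waveform(samples, float(rate))


def write_wav(path, wav: Waveform, dtype: str = "int16") -> None:
    """Write a Waveform as PCM WAV (int16 by default, or 'float32')."""
    x = np.clip(wav.samples, -1.0, 1.0)
    if dtype == "int16":
        data = np.round(x * 32767.0).astype(np.int16)
    elif dtype == "float32":
        data = x.astype(np.float32)
    else:
        raise ValueError(f"unsupported WAV dtype {dtype!r}")
    scipy.io.wavfile.write(path, int(round(wav.rate)), data)


# ---------------------------------------------------------------------------
# TextGrid


def _decode_textgrid_bytes(raw: bytes) -> str:
    if raw.startswith(b"\xfe\xff") or raw.startswith(b"\xff\xfe"):
        return raw.decode("utf-16")
    return raw.decode("utf-8-sig")


_NUM_RE = re.compile(r"=\s*([-+0-9.eE]+)")
_STR_RE = re.compile(r'=\s*"(.*)"\s*$', re.DOTALL)


def _unquote(s: str) -> str:
    return s.replace('""', '"')


class _TokenStream:
    """Sequential value extractor shared by the long- and short-format parsers.

    In the long format every value sits after '=' (numbers bare, strings quoted);
    in the short format each value is alone on its line. Structural lines
    ('item [1]:', 'intervals: size = 3') are handled by the callers.
    """

    def __init__(self, lines: list[str]):
        self.lines = lines
        self.pos = 0

    def peek(self) -> str:
        while self.pos < len(self.lines) and not self.lines[self.pos].strip():
            self.pos += 1
        if self.pos >= len(self.lines):
            raise TextGridParseError(f"unexpected end of file at line {self.pos + 1}")
        return self.lines[self.pos].strip()

    def next_line(self) -> str:
        line = self.peek()
        self.pos += 1
        return line

    def next_number(self) -> float:
        line = self.next_line()
        m = _NUM_RE.search(line)
        token = m.group(1) if m else line
        try:
            return float(token)
        except ValueError:
            raise TextGridParseError(
                f"line {self.pos}: expected a number, got {line!r}"
            ) from None

    def next_string(self) -> str:
        # Quoted strings may contain newlines; keep consuming until the quote closes.
        line = self.next_line()
        if "=" in line:
            m = _STR_RE.search(line)
            if m is not None:
                return _unquote(m.group(1))
            start = line.index("=") + 1
            text = line[start:].lstrip()
        else:
            text = line
        if not text.startswith('"'):
            raise TextGridParseError(f"line {self.pos}: expected a quoted string, got {line!r}")
        body = text[1:]
        while not (body.endswith('"') and not body.endswith('""')) or body == '"' * len(body):
            # handle escaped quotes: a line ending in an odd run of quotes terminates
            stripped = body.rstrip('"')
            nquotes = len(body) - len(stripped)
            if nquotes % 2 == 1:
                break
            body += "\n" + self.next_line()
        return _unquote(body[:-1])


def read_textgrid(path) -> list[IntervalTier]:
    """Read all interval tiers from a Praat TextGrid (long or short text format).

    Point (text) tiers are skipped with a logged warning. Times are seconds.
    """
    with open(path, "rb") as fh:
        text = _decode_textgrid_bytes(fh.read())
    lines = text.splitlines()
    if len(lines) < 2 or "ooTextFile" not in lines[0] or "TextGrid" not in lines[1]:
        bad = 1 if (lines and "ooTextFile" in lines[0]) else 0
        raise TextGridParseError(
            f"line {bad + 1}: not a Praat TextGrid header: {lines[bad] if bad < len(lines) else '<missing>'!r}"
        )
    ts = _TokenStream(lines)
    ts.pos = 2
    ts.next_number()  # global xmin
    ts.next_number()  # global xmax
    exists_line = ts.next_line()  # '<exists>' / 'tiers? <exists>'
    if "<exists>" not in exists_line and "<absent>" not in exists_line:
        raise TextGridParseError(f"line {ts.pos}: expected tiers flag, got {exists_line!r}")
    if "<absent>" in exists_line:
        return []
    n_tiers = int(ts.next_number())
    tiers: list[IntervalTier] = []
    for _ in range(n_tiers):
        # long format: skip 'item []:' (global) and 'item [k]:' (per-tier) headers
        while ts.peek().startswith("item"):
            ts.next_line()
        klass = ts.next_string()
        name = ts.next_string()
        ts.next_number()  # tier xmin
        ts.next_number()  # tier xmax
        n_items = int(ts.next_number())
        if klass == "IntervalTier":
            intervals = []
            for _ in range(n_items):
                if ts.peek().startswith("intervals ["):
                    ts.next_line()
                x0 = ts.next_number()
                x1 = ts.next_number()
                label = ts.next_string()
                if x1 > x0:
                    intervals.append(Interval(x0, x1, label))
            tiers.append(IntervalTier(name, intervals))
        elif klass == "TextTier":
            logger.warning("TextGrid %s: skipping point tier %r", path, name)
            for _ in range(n_items):
                if ts.peek().startswith("points ["):
                    ts.next_line()
                ts.next_number()
                ts.next_string()
        else:
            raise TextGridParseError(f"line {ts.pos}: unknown tier class {klass!r}")
    return tiers


def _tile_tier(tier: IntervalTier, xmin: float, xmax: float) -> list[Interval]:
    """Fill gaps with empty-label intervals so the tier partitions [xmin, xmax]."""
    tier.validate()
    out: list[Interval] = []
    cursor = xmin
    for iv in tier.intervals:
        if iv.start < xmin - 1e-9 or iv.end > xmax + 1e-9:
            raise ValueError(
                f"tier {tier.name!r}: interval [{iv.start},{iv.end}] outside [{xmin},{xmax}]"
            )
        if iv.start > cursor + 1e-9:
            out.append(Interval(cursor, iv.start, ""))
        out.append(iv)
        cursor = iv.end
    if xmax > cursor + 1e-9:
        out.append(Interval(cursor, xmax, ""))
    return out


def _quote(s: str) -> str:
    return '"' + s.replace('"', '""') + '"'


def write_textgrid(tiers: list[IntervalTier], path, xmin: float = 0.0, xmax: float | None = None) -> None:
    """Write interval tiers as a long-format UTF-8 Praat TextGrid.

    Gaps are filled with empty-label intervals so every tier tiles [xmin, xmax].
    """
    if xmax is None:
        ends = [iv.end for t in tiers for iv in t.intervals]
        xmax = max(ends) if ends else xmin + 1.0
    for t in tiers:
        for iv in t.intervals:
            if iv.end > xmax + 1e-9:
                raise ValueError(f"xmax {xmax} < interval end {iv.end} in tier {t.name!r}")
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        f"xmin = {xmin:.6f}",
        f"xmax = {xmax:.6f}",
        "tiers? <exists>",
        f"size = {len(tiers)}",
        "item []:",
    ]
    for ti, tier in enumerate(tiers, start=1):
        tiled = _tile_tier(tier, xmin, xmax)
        lines += [
            f"    item [{ti}]:",
            '        class = "IntervalTier"',
            f"        name = {_quote(tier.name)}",
            f"        xmin = {xmin:.6f}",
            f"        xmax = {xmax:.6f}",
            f"        intervals: size = {len(tiled)}",
        ]
        for ii, iv in enumerate(tiled, start=1):
            lines += [
                f"        intervals [{ii}]:",
                f"            xmin = {iv.start:.6f}",
                f"            xmax = {iv.end:.6f}",
                f"            text = {_quote(iv.label)}",
            ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
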