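"""Query-by-example behaviour labelling by (normalized) cross-correlation.

A behaviour template is a short multichannel waveform cut from (or saved
for) a deployment.  Sliding it across the series and scoring the similarity
at every position turns classification into search: positions scoring above
a user-chosen threshold become candidate behaviour instances, which the
analyst accepts, rejects or complements with manual labels.

Similarity is normalized cross-correlation (NCC): template and window are
made zero-mean and unit-norm per channel so gain and offset changes do not
affect the score, per-channel correlations are averaged, and the result
``r`` in [-1, 1] is reported as a percentage ``(r + 1) / 2 * 100`` — 100 %
is an exact (shape) match, 0 % maximal anti-correlation.  The sliding dot
products are evaluated in frequency space (FFT convolution with running
window sums), numerically equivalent to the direct sliding correlation but
linear-logarithmic in the series length.  An unnormalized mode returns the
raw sliding correlation (amplitude-aware) instead.

Templates can be resampled (polyphase interpolation ``p`` / decimation
``q``) to search for the same behaviour at different durations, and several
templates of one behaviour can be pooled ("boosting") to widen the search
span.  A file-backed :class:`TemplateStore` keeps templates per animal and
behaviour for reuse across deployments.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import scipy.signal

__all__ = [
    "Template",
    "MatchResult",
    "BehaviourClass",
    "LabelledInterval",
    "LabelSet",
    "TemplateStore",
    "resample",
    "sliding_similarity",
    "extract_matches",
    "boost",
]

#: default similarity threshold (percent) for match extraction
DEFAULT_THRESHOLD = 85.0

#: relative variance floor below which a window counts as flat (similarity 0)
_VAR_EPS = 1e-12


@dataclass(frozen=True)
class Template:
    """A multichannel query waveform with metadata.

    ``waveform`` maps channel name -> 1-D array; all channels share the same
    length L >= 2.  ``interp``/``decim`` record the resampling factors the
    template should be searched at.
    """

    name: str
    waveform: dict[str, np.ndarray]
    animal: str = ""
    interp: int = 1
    decim: int = 1

    def __post_init__(self) -> None:
        if not self.waveform:
            raise ValueError("template needs at least one channel")
        wf = {k: np.asarray(v, dtype=float) for k, v in self.waveform.items()}
        lengths = {len(v) for v in wf.values()}
        if len(lengths) != 1:
            raise ValueError("all template channels must have the same length")
        if lengths.pop() < 2:
            raise ValueError("template length must be at least 2 samples")
        if self.interp < 1 or self.decim < 1:
            raise ValueError("resampling factors must be positive integers")
        object.__setattr__(self, "waveform", wf)

    @property
    def channels(self) -> list[str]:
        return list(self.waveform)

    @property
    def length(self) -> int:
        return len(next(iter(self.waveform.values())))

    def resampled(self) -> "Template":
        """The template at its own interp/decim factors."""
        if self.interp == self.decim:
            return self
        wf = {k: resample(v, self.interp, self.decim) for k, v in self.waveform.items()}
        return Template(self.name, wf, animal=self.animal)


@dataclass(frozen=True)
class MatchResult:
    """One candidate behaviour instance found by template search."""

    start: int
    length: int
    similarity: float
    template: str = ""

    @property
    def end(self) -> int:
        return self.start + self.length

    def overlaps(self, other: "MatchResult") -> bool:
        return self.start < other.end and other.start < self.end


def resample(waveform: np.ndarray, p: int, q: int) -> np.ndarray:
    """Resample by the rational factor ``p / q`` (low-pass interpolation then
    decimation); output length ``round(L * p / q)``.

    ``p == q`` is the identity; resampling by 1/2 halves the sampling rate,
    by 2/1 doubles the duration.
    """
    if p < 1 or q < 1:
        raise ValueError("interpolation and decimation factors must be >= 1")
    x = np.asarray(waveform, dtype=float)
    L = x.shape[0]
    target = round(L * p / q)
    if target < 2:
        raise ValueError(f"resampling {L} samples by {p}/{q} leaves fewer than 2 samples")
    frac = Fraction(p, q)
    if frac == 1:
        return x.copy()
    y = scipy.signal.resample_poly(x, frac.numerator, frac.denominator, axis=0, padtype="line")
    return y[:target]


def _sliding_sums(x: np.ndarray, L: int) -> tuple[np.ndarray, np.ndarray]:
    """Running window sums of x and x**2 over every length-L window."""
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    return c1[L:] - c1[:-L], c2[L:] - c2[:-L]


def _channel_scores(x: np.ndarray, t: np.ndarray, normalized: bool) -> tuple[np.ndarray, np.ndarray]:
    """Per-position correlation of one channel; returns (score, flat window mask)."""
    L = len(t)
    if normalized:
        tz = t - t.mean()
        tn = float(np.linalg.norm(tz))
        if tn == 0.0:
            raise ValueError("template channel has zero variance; shape matching undefined")
        cross = scipy.signal.fftconvolve(x, tz[::-1], mode="valid")
        s1, s2 = _sliding_sums(x, L)
        var = np.maximum(s2 - s1 * s1 / L, 0.0)
        scale = np.maximum(s2 / L, 1.0)
        flat = var <= _VAR_EPS * L * scale
        denom = np.sqrt(var) * tn
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(flat, 0.0, cross / np.where(flat, 1.0, denom))
        return np.clip(r, -1.0, 1.0), flat
    cross = scipy.signal.fftconvolve(x, t[::-1], mode="valid")
    return cross, np.zeros(len(cross), dtype=bool)


def sliding_similarity(series, template: Template, normalized: bool = True) -> np.ndarray:
    """Similarity of the template at every start position of the series.

    Parameters
    ----------
    series : mapping or DataFrame
        Channel name -> 1-D array; must contain every template channel, each
        at least as long as the template.
    template : Template
        The query waveform (its interp/decim resampling is applied first).
    normalized : bool
        If True (default) return percentages in [0, 100] from the
        channel-averaged NCC; flat (zero-variance) windows score 0.  If
        False return the raw summed sliding correlation in signal units.

    The output has ``N - L + 1`` values, one per valid start position.
    """
    tpl = template.resampled()
    L = tpl.length
    scores = None
    flat_any = None
    for ch in tpl.channels:
        if ch not in series:
            raise ValueError(f"series lacks template channel {ch!r}")
        x = np.asarray(series[ch], dtype=float)
        if len(x) < L:
            raise ValueError(f"series channel {ch!r} shorter than the template")
        r, flat = _channel_scores(x, tpl.waveform[ch], normalized)
        scores = r if scores is None else scores + r
        flat_any = flat if flat_any is None else (flat_any | flat)
    scores = scores / len(tpl.channels)
    if normalized:
        pct = (scores + 1.0) / 2.0 * 100.0
        return np.where(flat_any, 0.0, pct)
    return scores


def extract_matches(
    similarity: np.ndarray,
    threshold: float,
    template_length: int,
    template: str = "",
    suppress_overlap: bool = True,
) -> list[MatchResult]:
    """Positions scoring at or above the threshold, overlap-suppressed.

    Candidates with ``similarity >= threshold`` are reduced by non-maximum
    suppression so accepted windows do not overlap: the highest similarity
    wins, ties resolve to the earliest start.  Results are sorted by start.
    Set ``suppress_overlap=False`` to keep every above-threshold position.
    """
    sim = np.asarray(similarity, dtype=float)
    cand = np.flatnonzero(sim >= threshold)
    results = [MatchResult(int(i), int(template_length), float(sim[i]), template) for i in cand]
    if not suppress_overlap:
        return results
    return _non_maximum_suppression(results)


def _non_maximum_suppression(results: list[MatchResult]) -> list[MatchResult]:
    accepted: list[MatchResult] = []
    ends: list[tuple[int, int]] = []  # accepted (start, end), kept sorted
    for r in sorted(results, key=lambda m: (-m.similarity, m.start)):
        if not any(r.start < e and s < r.end for s, e in ends):
            accepted.append(r)
            ends.append((r.start, r.end))
    return sorted(accepted, key=lambda m: m.start)


def boost(
    templates: list[Template],
    series,
    threshold: float = DEFAULT_THRESHOLD,
    normalized: bool = True,
    suppress_overlap: bool = True,
) -> list[MatchResult]:
    """Search with several example templates of one behaviour at once.

    The per-template above-threshold candidates are pooled and jointly
    overlap-suppressed, widening the search span beyond any single example.
    Duplicate templates contribute nothing new.
    """
    if not templates:
        raise ValueError("at least one template is required")
    pool: list[MatchResult] = []
    seen: set[tuple] = set()
    for tpl in templates:
        key = tuple((ch, tpl.waveform[ch].tobytes()) for ch in sorted(tpl.channels)) + (tpl.interp, tpl.decim)
        if key in seen:
            continue
        seen.add(key)
        sim = sliding_similarity(series, tpl, normalized=normalized)
        pool.extend(extract_matches(sim, threshold, tpl.resampled().length, template=tpl.name, suppress_overlap=False))
    if suppress_overlap:
        return _non_maximum_suppression(pool)
    return sorted(pool, key=lambda m: m.start)


@dataclass(frozen=True)
class BehaviourClass:
    id: int
    name: str
    colour: str = "#1f77b4"


@dataclass(frozen=True)
class LabelledInterval:
    """Half-open sample interval [start, end) carrying one behaviour class."""

    start: int
    end: int
    class_id: int
    provenance: str = "matched"  # or "manual"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("interval start must precede its end")
        if self.provenance not in ("matched", "manual"):
            raise ValueError("provenance must be 'matched' or 'manual'")


class LabelSet:
    """Classified behaviour intervals plus the accept/reject bookkeeping.

    Matches found by a search enter a pending queue; the analyst accepts
    them into a class or rejects them.  Rejected intervals are remembered so
    a re-run of the same search does not resurrect them; manual labels
    override rejections.  Class codes are small integers assigned in
    creation order starting at 1, with 0 reserved for "unlabelled" in
    exports.
    """

    def __init__(self) -> None:
        self.classes: dict[int, BehaviourClass] = {}
        self.intervals: list[LabelledInterval] = []
        self.rejected: list[tuple[int, int]] = []
        self.pending: list[MatchResult] = []

    # -- classes ---------------------------------------------------------
    def add_class(self, name: str, colour: str | None = None) -> BehaviourClass:
        cid = max(self.classes, default=0) + 1
        cls = BehaviourClass(cid, name, colour or f"C{cid}")
        self.classes[cid] = cls
        return cls

    # -- search plumbing -------------------------------------------------
    def add_pending(self, matches: list[MatchResult]) -> int:
        """Queue new matches, silently dropping previously rejected intervals
        and intervals already labelled identically."""
        added = 0
        existing = {(iv.start, iv.end) for iv in self.intervals}
        queued = {(m.start, m.end) for m in self.pending}
        for m in matches:
            key = (m.start, m.end)
            if key in existing or key in queued:
                continue
            if any(m.start < e and s < m.end for s, e in self.rejected):
                continue
            self.pending.append(m)
            queued.add(key)
            added += 1
        return added

    def accept(self, indices: list[int], class_id: int) -> None:
        """Move pending matches (by queue index) into a class."""
        if class_id not in self.classes:
            raise KeyError(f"unknown behaviour class {class_id}")
        bad = [i for i in indices if not 0 <= i < len(self.pending)]
        if bad:
            raise KeyError(f"unknown pending match ids {bad}")
        for i in sorted(set(indices), reverse=True):
            m = self.pending.pop(i)
            self._insert(LabelledInterval(m.start, m.end, class_id, "matched"))

    def accept_all(self, class_id: int) -> None:
        self.accept(list(range(len(self.pending))), class_id)

    def reject(self, indices: list[int]) -> None:
        bad = [i for i in indices if not 0 <= i < len(self.pending)]
        if bad:
            raise KeyError(f"unknown pending match ids {bad}")
        for i in sorted(set(indices), reverse=True):
            m = self.pending.pop(i)
            self.rejected.append((m.start, m.end))

    def reject_region(self, start: int, end: int) -> int:
        """Reject every pending match overlapping a clipped time region."""
        if start >= end:
            raise ValueError("region start must precede its end")
        keep, dropped = [], 0
        for m in self.pending:
            if m.start < end and start < m.end:
                dropped += 1
            else:
                keep.append(m)
        self.pending = keep
        self.rejected.append((start, end))
        return dropped

    # -- manual labelling ------------------------------------------------
    def manual_label(self, start: int, end: int, class_id: int) -> None:
        """Label a sample range by hand; allowed even inside rejected regions
        (the analyst's direct call overrides past rejections)."""
        if class_id not in self.classes:
            raise KeyError(f"unknown behaviour class {class_id}")
        self._insert(LabelledInterval(int(start), int(end), class_id, "manual"))

    def _insert(self, iv: LabelledInterval) -> None:
        for other in self.intervals:
            if other.class_id != iv.class_id and iv.start < other.end and other.start < iv.end:
                raise ValueError(
                    f"label [{iv.start}, {iv.end}) of class {iv.class_id} overlaps "
                    f"[{other.start}, {other.end}) of class {other.class_id}"
                )
        # union overlapping/adjacent intervals of the same class
        merged_start, merged_end, prov = iv.start, iv.end, iv.provenance
        keep = []
        for other in self.intervals:
            if other.class_id == iv.class_id and merged_start <= other.end and other.start <= merged_end:
                merged_start = min(merged_start, other.start)
                merged_end = max(merged_end, other.end)
                if other.provenance == "manual":
                    prov = "manual"
            else:
                keep.append(other)
        keep.append(LabelledInterval(merged_start, merged_end, iv.class_id, prov))
        self.intervals = sorted(keep, key=lambda v: v.start)

    # -- export ----------------------------------------------------------
    def behaviour_codes(self, n_rows: int) -> np.ndarray:
        """Integer behaviour code per row: class id inside labels, else 0."""
        codes = np.zeros(n_rows, dtype=np.int64)
        for iv in self.intervals:
            if iv.start < 0 or iv.end > n_rows:
                raise ValueError(f"label [{iv.start}, {iv.end}) exceeds the {n_rows}-row table")
            codes[iv.start : iv.end] = iv.class_id
        return codes


class TemplateStore:
    """File-backed template database: a directory of plain-text template
    files with a JSON index keyed animal -> behaviour name."""

    INDEX = "index.json"

    def __init__(self, root: str) -> None:
        self.root = str(root)
        os.makedirs(self.root, exist_ok=True)
        self._index_path = os.path.join(self.root, self.INDEX)
        if os.path.exists(self._index_path):
            with open(self._index_path) as fh:
                self._index: dict[str, dict[str, str]] = json.load(fh)
        else:
            self._index = {}

    def _save_index(self) -> None:
        with open(self._index_path, "w") as fh:
            json.dump(self._index, fh, indent=1, sort_keys=True)

    def store(self, template: Template) -> str:
        """Persist a template under its animal/behaviour keys; returns the
        file name used."""
        safe = "".join(c if c.isalnum() or c in "-_" else "_" for c in f"{template.animal}__{template.name}")
        fname = f"{safe}.tpl"
        write_template(template, os.path.join(self.root, fname))
        self._index.setdefault(template.animal, {})[template.name] = fname
        self._save_index()
        return fname

    def query(self, animal: str, behaviour: str | None = None) -> list[Template]:
        """All templates for an animal, or the one named behaviour.

        Unknown animals yield an empty list; an unknown behaviour for a
        known animal raises ``KeyError``.
        """
        entry = self._index.get(animal)
        if entry is None:
            return []
        if behaviour is not None:
            if behaviour not in entry:
                raise KeyError(f"no template {behaviour!r} stored for animal {animal!r}")
            names = [behaviour]
        else:
            names = sorted(entry)
        return [read_template(os.path.join(self.root, entry[n])) for n in names]


def write_template(template: Template, path) -> None:
    """Template file: metadata header lines then one data line per channel."""
    with open(path, "w") as fh:
        fh.write("# behaviour template\n")
        fh.write(f"name: {template.name}\n")
        fh.write(f"animal: {template.animal}\n")
        fh.write(f"interp: {template.interp}\n")
        fh.write(f"decim: {template.decim}\n")
        fh.write(f"channels: {','.join(template.channels)}\n")
        for ch in template.channels:
            fh.write(f"data {ch}: " + " ".join(repr(float(v)) for v in template.waveform[ch]) + "\n")


def read_template(path) -> Template:
    meta: dict[str, str] = {}
    data: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            key, _, rest = line.partition(":")
            key = key.strip()
            if key.startswith("data "):
                data[key[5:].strip()] = np.array([float(t) for t in rest.split()])
            else:
                meta[key] = rest.strip()
    if "channels" not in meta or not data:
        raise ValueError(f"malformed template file {path!r}")
    order = [c for c in meta["channels"].split(",") if c]
    return Template(
        name=meta.get("name", ""),
        waveform={c: data[c] for c in order},
        animal=meta.get("animal", ""),
        interp=int(meta.get("interp", 1)),
        decim=int(meta.get("decim", 1)),
    )
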