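"""Unsupervised "neural code" waveform classification.

Recurring spike-waveform shapes are catalogued in a template library. Each
incoming peak-aligned waveform is compared digit-by-digit (sample-by-sample,
walking outward from the alignment point) against each existing template in
library order: a sample position is *consistent* when its deviation from
the template, relative to the template's peak amplitude, is within a
tolerance (default 30%). A waveform whose fraction of consistent samples
reaches the consistency minimum (default 90%) joins that code; otherwise it
founds a new code whose standard template it becomes (first-waveform-as-
template rule). A recording is then summarised by its code-frequency
profile, and profiles are compared by per-code frequency deltas plus a
chi-square test on the count tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from neurocode.errors import ConfigError, ValidationError
from neurocode.detect import Waveform

_EPS = 1e-9


@dataclass
class CodeTemplate:
    """One neural-code class: founding template plus member envelope."""

    code_id: str
    template_uv: np.ndarray
    alignment_index: int
    n_members: int = 1
    envelope_min: np.ndarray = None
    envelope_max: np.ndarray = None

    def __post_init__(self):
        self.template_uv = np.asarray(self.template_uv, dtype=float)
        if self.envelope_min is None:
            self.envelope_min = self.template_uv.copy()
        if self.envelope_max is None:
            self.envelope_max = self.template_uv.copy()
        self.envelope_min = np.asarray(self.envelope_min, dtype=float)
        self.envelope_max = np.asarray(self.envelope_max, dtype=float)
        if self.n_members < 1:
            raise ValidationError("n_members must be >= 1")
        if np.any(self.envelope_min > self.template_uv + 1e-12) or np.any(
            self.envelope_max < self.template_uv - 1e-12
        ):
            raise ValidationError("envelope must contain the template")

    def update_envelope(self, samples_uv: np.ndarray) -> None:
        self.envelope_min = np.minimum(self.envelope_min, samples_uv)
        self.envelope_max = np.maximum(self.envelope_max, samples_uv)


@dataclass
class CodeLibrary:
    """Ordered list of code templates with the matching parameters."""

    codes: list[CodeTemplate] = field(default_factory=list)
    tolerance: float = 0.30
    consistency_min: float = 0.90

    def __post_init__(self):
        if not (0 < self.tolerance < 1):
            raise ConfigError("tolerance must be in (0, 1)")
        if not (0 < self.consistency_min <= 1):
            raise ConfigError("consistency_min must be in (0, 1]")
        ids = [c.code_id for c in self.codes]
        if len(set(ids)) != len(ids):
            raise ValidationError("code_ids must be unique")

    def __len__(self) -> int:
        return len(self.codes)

    def next_code_id(self) -> str:
        return f"C{len(self.codes) + 1:03d}"

    def get(self, code_id: str) -> CodeTemplate:
        for c in self.codes:
            if c.code_id == code_id:
                return c
        raise KeyError(code_id)


@dataclass
class CodeProfile:
    """Relative code frequencies for one recording/corpus."""

    frequencies: dict[str, float]
    total_events: int
    top_codes: list[str] = field(default_factory=list)


def _standardize_length(
    w: np.ndarray, align: int, length: int, target_align: int
) -> np.ndarray:
    """Centre-crop / zero-pad a waveform to the library's standard window."""
    out = np.zeros(length)
    src_lo = align - target_align
    for j in range(length):
        k = src_lo + j
        if 0 <= k < w.size:
            out[j] = w[k]
    return out


def sample_consistency(
    waveform: np.ndarray, template: np.ndarray, tolerance: float = 0.30
) -> float:
    """Fraction of sample positions consistent with the template.

    Deviation at each position is measured relative to the template's peak
    amplitude (not the per-sample value — division near zero-crossings would
    be unstable): position j is consistent when
    ``|w_j - t_j| / max(|t_peak|, eps) <= tolerance``. Positions are
    scanned outward from the alignment point; the fraction itself is
    order-independent.
    """
    w = np.asarray(waveform, dtype=float)
    t = np.asarray(template, dtype=float)
    if w.shape != t.shape:
        raise ValidationError(
            f"length mismatch: waveform {w.size}, template {t.size}"
        )
    peak = max(np.max(np.abs(t)), _EPS)
    ok = np.abs(w - t) / peak <= tolerance
    return float(ok.mean())


def classify_waveform(
    waveform: Waveform | np.ndarray,
    library: CodeLibrary,
    best_match: bool = False,
) -> str:
    """Assign a waveform to a library code, creating a new code if unmatched.

    Default policy is first-match-wins in library order (sequential template
    growth); ``best_match=True`` assigns to the maximum-consistency template
    among those reaching the consistency minimum instead.
    """
    if isinstance(waveform, Waveform):
        samples, align = waveform.samples_uv, waveform.alignment_index
    else:
        samples = np.asarray(waveform, dtype=float)
        align = int(np.argmax(np.abs(samples)))

    best_id, best_score = None, -1.0
    for tmpl in library.codes:
        w = samples
        if w.size != tmpl.template_uv.size or align != tmpl.alignment_index:
            warnings.warn(
                "waveform window differs from library standard; cropping/padding"
            )
            w = _standardize_length(
                samples, align, tmpl.template_uv.size, tmpl.alignment_index
            )
        score = sample_consistency(w, tmpl.template_uv, library.tolerance)
        if score >= library.consistency_min:
            if not best_match:
                tmpl.n_members += 1
                tmpl.update_envelope(w)
                return tmpl.code_id
            if score > best_score:
                best_id, best_score = tmpl.code_id, score

    if best_id is not None:
        tmpl = library.get(best_id)
        tmpl.n_members += 1
        tmpl.update_envelope(samples)
        return best_id

    code_id = library.next_code_id()
    library.codes.append(
        CodeTemplate(
            code_id=code_id,
            template_uv=samples.copy(),
            alignment_index=align,
        )
    )
    return code_id


def build_codebook(
    waveforms: list[Waveform] | list[np.ndarray],
    tolerance: float = 0.30,
    consistency_min: float = 0.90,
    best_match: bool = False,
) -> tuple[CodeLibrary, list[str]]:
    """Sequential single pass over the input order.

    The first waveform founds code C001; each subsequent waveform is
    classified against the growing library. Returns the library and the
    per-input assignment list. The result depends on input order (the
    founding waveform of each code is the first one seen).
    """
    library = CodeLibrary(tolerance=tolerance, consistency_min=consistency_min)
    assignments = [
        classify_waveform(w, library, best_match=best_match) for w in waveforms
    ]
    return library, assignments


def code_profile(assignments: list[str], top_k: int | None = None) -> CodeProfile:
    """Normalised code frequencies; top_k by frequency, ties by code_id."""
    if len(assignments) == 0:
        raise ValidationError("no assignments to profile")
    ids, counts = np.unique(np.asarray(assignments, dtype=object), return_counts=True)
    total = int(counts.sum())
    freqs = {str(i): float(c) / total for i, c in zip(ids, counts)}
    order = sorted(freqs, key=lambda k: (-freqs[k], k))
    if top_k is None:
        top = order
    else:
        if top_k > len(order):
            warnings.warn(
                f"top_k={top_k} exceeds {len(order)} codes; returning all"
            )
        top = order[:top_k]
    return CodeProfile(frequencies=freqs, total_events=total, top_codes=top)


def compare_profiles(profile_a: CodeProfile, profile_b: CodeProfile) -> dict:
    """Per-code frequency deltas (b - a) plus a chi-square homogeneity test.

    The code universe is the union (absent codes count 0). The chi-square
    statistic is computed on the 2 x k count table with the standard
    ``(k - 1)`` degrees of freedom.
    """
    if profile_a.total_events == 0 or profile_b.total_events == 0:
        raise ValidationError("cannot compare profiles with zero totals")
    universe = sorted(set(profile_a.frequencies) | set(profile_b.frequencies))
    fa = np.array([profile_a.frequencies.get(c, 0.0) for c in universe])
    fb = np.array([profile_b.frequencies.get(c, 0.0) for c in universe])
    deltas = {c: float(d) for c, d in zip(universe, fb - fa)}
    ca = np.rint(fa * profile_a.total_events)
    cb = np.rint(fb * profile_b.total_events)
    if np.allclose(ca, cb) and profile_a.total_events == profile_b.total_events:
        chi2, p, dof = 0.0, 1.0, len(universe) - 1
    else:
        table = np.vstack([ca, cb])
        # drop all-zero columns (degenerate under chi-square)
        table = table[:, table.sum(axis=0) > 0]
        chi2, p, dof, _ = stats.chi2_contingency(table)
    return {
        "codes": universe,
        "delta": deltas,
        "chi2": float(chi2),
        "p": float(p),
        "dof": int(dof),
    }
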