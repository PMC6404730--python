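"""TBP–promoter binding-affinity estimation.

The model follows the three-step picture of TBP–promoter recognition:
(i) TBP slides along the DNA duplex, (ii) stops at a putative TBP-binding
site (TATA box), and (iii) the complex is fixed by DNA bending.  Each step
contributes one raw sequence score over a candidate window:

* ``stop``  — an additive position-weight-matrix (PWM) score of the window;
* ``slide`` — the mean of a dinucleotide sliding/deformability property
  over the window's overlapping dinucleotide steps;
* ``bend``  — likewise for a dinucleotide bending-propensity property.

Each raw term is mapped onto a common −ln(K_D) scale by a per-step linear
calibration ``E_i = a_i + b_i · f_i``.  The window estimate is the
unweighted mean of the three calibrated terms; the promoter estimate is the
maximum over all windows, and the attached uncertainty δ is the sample
standard deviation of the three calibrated terms at the maximizing window
divided by √3 (the standard error of their mean).  δ is therefore a
between-method disagreement: it is exactly zero when the three partial
estimates coincide.

All numeric content of the model — PWM, property tables, calibration — is
configuration (see :class:`ModelConfig` and the packaged default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError, InputError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: IUPAC ambiguity codes resolved (lenient mode) to their first base in
#: alphabetical order.
_IUPAC_FIRST = {
    "R": "A", "Y": "C", "S": "C", "W": "A", "K": "G", "M": "A",
    "B": "C", "D": "A", "H": "A", "V": "A", "N": "A",
}

DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)


def normalize_sequence(seq: str, *, lenient: bool = False) -> str:
    """Uppercase ``seq`` and enforce the A/C/G/T alphabet.

    In strict mode (default) IUPAC ambiguity codes raise :class:`InputError`;
    in lenient mode they are resolved to the first base in alphabetical
    order with a warning.
    """
    seq = seq.upper().replace("U", "T")
    if all(c in _BASE_INDEX for c in seq):
        return seq
    bad = sorted({c for c in seq if c not in _BASE_INDEX})
    unknown = [c for c in bad if c not in _IUPAC_FIRST]
    if unknown:
        raise InputError(f"non-nucleotide characters in sequence: {unknown}")
    if not lenient:
        raise InputError(
            f"ambiguous IUPAC codes {bad} rejected in strict mode "
            "(pass lenient=True to resolve them)"
        )
    warnings.warn(f"resolving ambiguity codes {bad} to first alphabetical base")
    return "".join(_IUPAC_FIRST.get(c, c) for c in seq)


@dataclass(frozen=True)
class PromoterRecord:
    """A gene's upstream promoter sequence in TSS-relative coordinates.

    ``start_offset`` is the TSS-relative position of the first base; the
    default −70 places a 70-bp sequence at offsets [−70, −1], i.e. the
    region immediately upstream of the transcription start site on the gene
    strand, written 5'→3'.
    """

    gene_id: str
    transcript_id: str
    sequence: str
    start_offset: int = -70

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))

    @property
    def end_offset(self) -> int:
        """TSS-relative position one past the last base."""
        return self.start_offset + len(self.sequence)

    def index_of(self, offset: int) -> int:
        """Map a TSS-relative offset to a 0-based index into ``sequence``."""
        i = offset - self.start_offset
        if not 0 <= i < len(self.sequence):
            raise InputError(
                f"offset {offset} outside promoter {self.gene_id} "
                f"[{self.start_offset}, {self.end_offset})"
            )
        return i


@dataclass(frozen=True)
class AffinityEstimate:
    """(−ln K_D, δ) for one allele, with the best-scoring window position.

    ``neg_log_kd`` is −ln(K_D) with K_D in the molar units of the
    calibration; larger means tighter TBP binding.  ``delta`` ≥ 0 is the
    uncertainty of the estimate; ``best_window_offset`` is the TSS-relative
    start of the maximizing window (leftmost on ties).
    """

    neg_log_kd: float
    delta: float
    best_window_offset: int

    @property
    def kd(self) -> float:
        """Equilibrium dissociation constant, exp(−neg_log_kd)."""
        return math.exp(-self.neg_log_kd)


class ModelConfig:
    """Numeric content of the three-step affinity model.

    Parameters
    ----------
    pwm
        4 × window_length weight matrix, row order A, C, G, T (stop step).
    slide_property, bend_property
        Dinucleotide → value tables covering all 16 dinucleotides.
    calibration
        Per-step linear maps ``{step: (a, b)}`` from raw term to the
        −ln K_D scale, steps "stop", "slide", "bend".
    significance_alpha_threshold
        Minimum confidence α = 1 − p for an allele difference to count as
        significant downstream (default 0.95).
    saturation
        Optional ceiling applied to every calibrated partial estimate.  A
        linear calibration is only meaningful within its anchored range,
        so the anchored default caps each term at the strong-site anchor:
        no window can be predicted to bind more tightly than the consensus
        TATA box.  ``None`` disables the cap.
    """

    STEPS = ("stop", "slide", "bend")

    def __init__(
        self,
        pwm: np.ndarray,
        slide_property: dict[str, float],
        bend_property: dict[str, float],
        calibration: dict[str, tuple[float, float]],
        significance_alpha_threshold: float = 0.95,
        saturation: float | None = None,
    ):
        pwm = np.asarray(pwm, dtype=float)
        if pwm.ndim != 2 or pwm.shape[0] != 4:
            raise ConfigError(f"pwm must be 4 x window_length, got {pwm.shape}")
        if pwm.shape[1] < 2:
            raise ConfigError("window_length must be >= 2")
        if not np.all(np.isfinite(pwm)):
            raise ConfigError("pwm contains non-finite weights")
        for name, table in (("slide", slide_property), ("bend", bend_property)):
            missing = [d for d in DINUCLEOTIDES if d not in table]
            if missing:
                raise ConfigError(f"{name}_property missing dinucleotides {missing}")
            if not all(math.isfinite(table[d]) for d in DINUCLEOTIDES):
                raise ConfigError(f"{name}_property contains non-finite values")
        for step in self.STEPS:
            if step not in calibration:
                raise ConfigError(f"calibration missing step {step!r}")
            a, b = calibration[step]
            if not (math.isfinite(a) and math.isfinite(b)):
                raise ConfigError(f"calibration for {step!r} not finite")
        if not 0.0 < significance_alpha_threshold < 1.0:
            raise ConfigError("significance_alpha_threshold must be in (0,1)")
        self.pwm = pwm
        self.slide_property = dict(slide_property)
        self.bend_property = dict(bend_property)
        self.calibration = {s: (float(a), float(b)) for s, (a, b) in calibration.items()}
        self.significance_alpha_threshold = float(significance_alpha_threshold)
        if saturation is not None and not math.isfinite(saturation):
            raise ConfigError("saturation must be finite or None")
        self.saturation = None if saturation is None else float(saturation)
        # 4x4 lookup arrays for the vectorised scan
        self._slide_arr = self._table_to_array(self.slide_property)
        self._bend_arr = self._table_to_array(self.bend_property)

    @staticmethod
    def _table_to_array(table: dict[str, float]) -> np.ndarray:
        arr = np.empty((4, 4))
        for d, v in table.items():
            arr[_BASE_INDEX[d[0]], _BASE_INDEX[d[1]]] = v
        return arr

    @property
    def window_length(self) -> int:
        return self.pwm.shape[1]

    def consensus(self) -> str:
        """The per-position argmax window, the global PWM maximizer."""
        return "".join(BASES[i] for i in self.pwm.argmax(axis=0))

    # -- serialisation ----------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        pwm_spec = d["pwm"]
        if "frequencies" in pwm_spec:
            freqs = np.asarray(pwm_spec["frequencies"], dtype=float).T
            if np.any(freqs <= 0):
                raise ConfigError("pwm frequencies must be positive")
            pwm = np.log(freqs / 0.25)
        else:
            pwm = np.asarray(pwm_spec["weights"], dtype=float)
        slide = {k: float(v) for k, v in d["slide_property"].items()}
        bend = {k: float(v) for k, v in d["bend_property"].items()}
        cal_spec = d.get("calibration", {})
        saturation = d.get("saturation")
        if "anchor_high" in cal_spec:
            cal = _anchored_calibration(
                pwm, slide, bend,
                float(cal_spec["anchor_high"]), float(cal_spec["anchor_low"]),
            )
            # the anchored calibration saturates at the strong-site anchor
            # unless explicitly overridden
            if "saturation" not in d:
                saturation = float(cal_spec["anchor_high"])
        else:
            cal = {s: (float(cal_spec[s]["a"]), float(cal_spec[s]["b"]))
                   for s in cls.STEPS}
        return cls(
            pwm=pwm,
            slide_property=slide,
            bend_property=bend,
            calibration=cal,
            significance_alpha_threshold=float(
                d.get("significance_alpha_threshold", 0.95)
            ),
            saturation=saturation,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "ModelConfig":
        """The packaged default TATA-box model."""
        text = resources.files("tatamark.data").joinpath("tbp_model.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))


def _anchored_calibration(
    pwm: np.ndarray,
    slide: dict[str, float],
    bend: dict[str, float],
    hi: float,
    lo: float,
) -> dict[str, tuple[float, float]]:
    """Two-point calibration of each step onto the −ln K_D scale.

    The PWM consensus window is anchored at ``hi`` (a strong TATA box) and
    a poly-G window of the same length at ``lo`` (nonspecific DNA).  At the
    consensus the three calibrated estimates therefore coincide exactly.
    """
    w = pwm.shape[1]
    consensus = "".join(BASES[i] for i in pwm.argmax(axis=0))
    polyg = "G" * w
    cal = {}
    for step, f in (
        ("stop", lambda s: pwm_score(s, pwm)),
        ("slide", lambda s: slide_term(s, slide)),
        ("bend", lambda s: bend_term(s, bend)),
    ):
        hi_raw, lo_raw = f(consensus), f(polyg)
        if hi_raw == lo_raw:
            raise ConfigError(f"degenerate anchors for step {step!r}")
        b = (hi - lo) / (hi_raw - lo_raw)
        cal[step] = (hi - b * hi_raw, b)
    return cal


# -- raw per-window terms -------------------------------------------------


def pwm_score(window: str, pwm: np.ndarray) -> float:
    """Additive column-wise PWM score of ``window`` (stop step)."""
    pwm = np.asarray(pwm, dtype=float)
    if len(window) != pwm.shape[1]:
        raise InputError(
            f"window length {len(window)} != pwm width {pwm.shape[1]}"
        )
    try:
        return float(sum(pwm[_BASE_INDEX[c], j] for j, c in enumerate(window)))
    except KeyError as e:
        raise InputError(f"ambiguous base {e.args[0]!r} in window") from None


def _dinuc_mean(window: str, table: dict[str, float]) -> float:
    if len(window) < 2:
        raise InputError("window must have length >= 2")
    steps = [window[i: i + 2] for i in range(len(window) - 1)]
    try:
        return float(sum(table[s] for s in steps) / len(steps))
    except KeyError as e:
        raise InputError(f"dinucleotide {e.args[0]!r} not in property table") from None


def slide_term(window: str, slide_property: dict[str, float]) -> float:
    """Mean sliding/deformability property over the window's dinucleotide steps."""
    return _dinuc_mean(window, slide_property)


def bend_term(window: str, bend_property: dict[str, float]) -> float:
    """Mean bending propensity over the window's dinucleotide steps."""
    return _dinuc_mean(window, bend_property)


# -- promoter-level estimate ----------------------------------------------


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy().view(np.uint8)


_CODE = np.full(256, -1, dtype=np.int64)
for _b, _i in _BASE_INDEX.items():
    _CODE[ord(_b)] = _i


def window_estimates(sequence: str, config: ModelConfig) -> np.ndarray:
    """Calibrated partial estimates for every window.

    Returns an array of shape (3, n_windows): rows are the calibrated stop,
    slide and bend estimates for each window start.
    """
    w = config.window_length
    if len(sequence) < w:
        raise InputError(
            f"sequence length {len(sequence)} < window length {w}"
        )
    idx = _CODE[_encode(sequence)]
    if idx.min() < 0:
        raise InputError("sequence contains non-ACGT characters")
    n = len(sequence) - w + 1
    sw = np.lib.stride_tricks.sliding_window_view(idx, w)
    stop_raw = config.pwm[sw, np.arange(w)].sum(axis=1)
    steps_slide = config._slide_arr[idx[:-1], idx[1:]]
    steps_bend = config._bend_arr[idx[:-1], idx[1:]]
    kernel = np.ones(w - 1) / (w - 1)
    slide_raw = np.convolve(steps_slide, kernel, mode="valid")[:n]
    bend_raw = np.convolve(steps_bend, kernel, mode="valid")[:n]
    out = np.empty((3, n))
    for row, (step, raw) in enumerate(
        (("stop", stop_raw), ("slide", slide_raw), ("bend", bend_raw))
    ):
        a, b = config.calibration[step]
        out[row] = a + b * raw
    if config.saturation is not None:
        np.minimum(out, config.saturation, out=out)
    return out


def estimate_affinity(promoter: PromoterRecord, config: ModelConfig) -> AffinityEstimate:
    """Max-over-windows combined affinity estimate for a promoter.

    For every window the combined score is the mean of the three calibrated
    step estimates; the reported −ln K_D is the maximum over windows
    (leftmost window on ties) and δ is the sample standard deviation of the
    three partial estimates at that window divided by √3.
    """
    partials = window_estimates(promoter.sequence, config)
    combined = partials.mean(axis=0)
    best = int(np.argmax(combined))  # argmax returns the leftmost maximum
    at_best = partials[:, best]
    delta = float(np.std(at_best, ddof=1) / math.sqrt(3))
    return AffinityEstimate(
        neg_log_kd=float(combined[best]),
        delta=delta,
        best_window_offset=promoter.start_offset + best,
    )
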