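"""Primer evaluation: sequence statistics, in silico PCR, standard curves.

In silico PCR locates every site where the forward primer matches one
strand and the reverse primer matches the opposite strand downstream; the
product length spans both primer footprints inclusively (5' end of the
forward binding site to the 5' end of the reverse binding site).  The
default binding rule is exact matching; when mismatches are allowed, the
three 3'-terminal bases of each primer must still match exactly (the
polymerase-extension clamp).

The qPCR standard curve is an ordinary least-squares fit of Ct on log10
template amount; amplification efficiency follows from the slope as
E = 100·(10^(−1/slope) − 1), i.e. a perfectly doubling reaction has slope
−1/log10(2) ≈ −3.3219 and E = 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError
from .genome_io import GenomeRecord

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_acgt(seq: str, what: str = "sequence") -> None:
    if not seq:
        raise ValidationError(f"empty {what}")
    if set(seq) - set("ACGT"):
        raise ValidationError(f"{what} contains non-ACGT letters: {seq!r}")


@dataclass
class PrimerPair:
    name: str
    forward_seq: str
    reverse_seq: str
    expected_size_bp: int | None = None

    def __post_init__(self) -> None:
        _check_acgt(self.forward_seq, f"{self.name} forward primer")
        _check_acgt(self.reverse_seq, f"{self.name} reverse primer")


@dataclass
class Amplicon:
    template_id: str
    start_1based: int
    end_1based: int
    length_bp: int
    strand_of_forward: str  # "+" or "-"
    forward_mismatches: int
    reverse_mismatches: int


@dataclass
class StandardCurve:
    slope: float
    intercept: float
    r_squared: float
    efficiency_percent: float | None


def primer_stats(seq: str) -> tuple[int, float, float]:
    """``(length, gc_percent, tm_celsius)`` for a single primer.

    Tm uses the Wallace rule 2(A+T)+4(G+C) below 14 nt and the
    64.9 + 41·(G+C−16.4)/N formula otherwise — a design filter, not a
    thermodynamic prediction.
    """
    _check_acgt(seq, "primer")
    n = len(seq)
    gc = sum(1 for ch in seq if ch in "GC")
    gc_percent = 100.0 * gc / n
    if n < 14:
        tm = 2.0 * (n - gc) + 4.0 * gc
    else:
        tm = 64.9 + 41.0 * (gc - 16.4) / n
    return n, gc_percent, tm


def efficiency_from_slope(slope: float) -> float | None:
    """Amplification efficiency in percent; ``None`` for non-negative slopes."""
    if slope >= 0:
        return None
    return 100.0 * (10.0 ** (-1.0 / slope) - 1.0)


def _binding_sites(primer: str, strand: str, max_mismatch: int) -> list[tuple[int, int]]:
    """(position, mismatches) of primer along one strand, 3'-clamp exact."""
    lp = len(primer)
    clamp = primer[-3:]
    out = []
    for i in range(len(strand) - lp + 1):
        if strand[i + lp - 3:i + lp] != clamp:
            continue
        mm = 0
        ok = True
        for x, y in zip(primer, strand[i:i + lp]):
            if x != y:
                mm += 1
                if mm > max_mismatch:
                    ok = False
                    break
        if ok:
            out.append((i, mm))
    return out


def _pcr_on_sequence(pair: PrimerPair, template: str, template_id: str,
                     max_mismatch: int, max_product_bp: int) -> list[Amplicon]:
    template = template.upper()
    length = len(template)
    minus = reverse_complement(template)
    lf, lr = len(pair.forward_seq), len(pair.reverse_seq)
    min_len = lf + lr
    fwd_plus = _binding_sites(pair.forward_seq, template, max_mismatch)
    rev_minus = _binding_sites(pair.reverse_seq, minus, max_mismatch)
    fwd_minus = _binding_sites(pair.forward_seq, minus, max_mismatch)
    rev_plus = _binding_sites(pair.reverse_seq, template, max_mismatch)

    out = []
    # forward on plus strand, reverse primer on minus strand downstream
    for i, fmm in fwd_plus:
        for j, rmm in rev_minus:
            rev_start_plus = length - j - lr  # plus-strand start of reverse site
            rev_end_plus = length - j - 1
            product = rev_end_plus - i + 1
            if rev_start_plus < i or product < min_len or product > max_product_bp:
                continue
            out.append(Amplicon(template_id, i + 1, rev_end_plus + 1, product,
                                "+", fmm, rmm))
    # forward on minus strand, reverse primer on plus strand upstream of it
    for i, fmm in fwd_minus:
        fwd_end_plus = length - i - 1
        for j, rmm in rev_plus:
            product = fwd_end_plus - j + 1
            if j + lr - 1 > fwd_end_plus or product < min_len \
                    or product > max_product_bp:
                continue
            out.append(Amplicon(template_id, j + 1, fwd_end_plus + 1, product,
                                "-", fmm, rmm))
    out.sort(key=lambda a: (a.start_1based, a.end_1based, a.strand_of_forward))
    return out


def in_silico_pcr(pair: PrimerPair, template, max_mismatch: int = 0,
                  max_product_bp: int = 3000,
                  template_id: str = "template") -> list[Amplicon]:
    """Predict PCR products of a primer pair on a template.

    ``template`` is a sequence string or a :class:`GenomeRecord`, in which
    case every CDS is scanned and amplicons carry ``genome:gene`` ids.  A
    primer longer than the template yields no products (not an error).
    """
    if max_mismatch < 0:
        raise ValidationError("max_mismatch must be >= 0")
    if isinstance(template, GenomeRecord):
        out = []
        for gene_id, seq in template.cds_nt.items():
            out.extend(_pcr_on_sequence(
                pair, seq, f"{template.genome_id}:{gene_id}",
                max_mismatch, max_product_bp,
            ))
        return out
    if not template:
        raise ValidationError("empty template")
    return _pcr_on_sequence(pair, template, template_id, max_mismatch,
                            max_product_bp)


def standard_curve(log10_inputs, ct_values) -> StandardCurve:
    """Fit Ct = slope·log10(amount) + intercept and derive the efficiency."""
    x = np.asarray(log10_inputs, dtype=float)
    y = np.asarray(ct_values, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("input and Ct lists differ in length")
    if x.size < 3:
        raise ValidationError("standard curve requires >= 3 points")
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in log10 inputs")
    fit = stats.linregress(x, y)
    eff = efficiency_from_slope(float(fit.slope))
    if eff is None:
        warnings.warn("non-negative standard-curve slope; efficiency undefined",
                      stacklevel=2)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        efficiency_percent=eff,
    )


@dataclass
class PrimerConstraints:
    """Window constraints for the primer scanner."""

    length_range: tuple[int, int] = (18, 24)
    gc_range: tuple[float, float] = (40.0, 60.0)
    tm_range: tuple[float, float] = (45.0, 65.0)
    product_range: tuple[int, int] = (80, 150)
    max_pairs: int = 10


def pick_primer_pairs(marker_seq: str,
                      constraints: PrimerConstraints | None = None,
                      ) -> list[PrimerPair]:
    """Enumerate primer pairs within a marker by exhaustive window scan.

    Forward windows are taken from the marker as-is, reverse primers as the
    reverse complement of downstream windows.  Windows must satisfy the
    length/GC/Tm constraints; pairs must produce a product inside
    ``product_range`` with non-overlapping footprints.  Pairs are ranked by
    forward/reverse Tm difference, then by position, and capped at
    ``max_pairs``.
    """
    constraints = constraints or PrimerConstraints()
    marker_seq = marker_seq.upper()
    _check_acgt(marker_seq, "marker")
    if len(marker_seq) < 60:
        raise ValidationError("marker too short for primer design (< 60 nt)")
    lo, hi = constraints.length_range
    gmin, gmax = constraints.gc_range
    tmin, tmax = constraints.tm_range

    def windows():
        for length in range(lo, hi + 1):
            for start in range(0, len(marker_seq) - length + 1):
                sub = marker_seq[start:start + length]
                _, gc, tm = primer_stats(sub)
                if gmin <= gc <= gmax and tmin <= tm <= tmax:
                    yield start, length, sub, tm

    accepted = list(windows())
    pmin, pmax = constraints.product_range
    pairs = []
    for f_start, f_len, f_seq, f_tm in accepted:
        for r_start, r_len, r_sub, r_tm in accepted:
            r_end = r_start + r_len - 1
            product = r_end - f_start + 1
            if r_start < f_start + f_len:
                continue
            if not pmin <= product <= pmax:
                continue
            pairs.append((abs(f_tm - r_tm), f_start, product,
                          f_seq, reverse_complement(r_sub)))
    pairs.sort(key=lambda p: (p[0], p[1], p[2], p[3]))
    out = []
    for i, (_, _, product, fwd, rev) in enumerate(pairs[:constraints.max_pairs]):
        out.append(PrimerPair(
            name=f"pair{i + 1:02d}", forward_seq=fwd, reverse_seq=rev,
            expected_size_bp=product,
        ))
    return out


def primer_pairs_from_frame(frame) -> list[PrimerPair]:
    """Build :class:`PrimerPair` objects from a primer table DataFrame."""
    out = []
    for row in frame.itertuples(index=False):
        size = getattr(row, "expected_size_bp", None)
        out.append(PrimerPair(
            name=str(row.name) if hasattr(row, "name") else str(row[0]),
            forward_seq=str(row.forward).replace(" ", "").upper(),
            reverse_seq=str(row.reverse).replace(" ", "").upper(),
            expected_size_bp=int(size) if size is not None and size == size else None,
        ))
    return out
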