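"""Rule-based inference of an SNV's probable origin from its cross-cell profile.

Without cell-matched DNA, the origin of an expressed SNV — inherited
(germline), acquired somatically by a cell subpopulation, or arising at the
RNA level (editing, transcriptional infidelity) — can only be inferred from
its expression pattern across cells:

* **germline homozygous** — every expressing cell shows only the variant
  allele, VAF_RNA ~ 1 throughout;
* **germline heterozygous** — balanced biallelic expression, VAF_RNA
  centered near 0.5 across cells;
* **somatic-like** — variant allele confined to a cell subset (a putative
  subclone), with transcription-consistent VAF among carrier cells;
* **RNA-origin-like** — sporadic low-count variant reads across cells, low
  VAF_RNA and low N_VAR.

The qualitative patterns are made operational through explicit numeric
thresholds (:class:`OriginThresholds`); every threshold is a tunable
parameter with a documented default, and rules are tried in fixed order
hom -> het -> somatic -> rna, first match wins.  Orthogonally, loci with
per-cell exclusively-one-allele expression split roughly evenly between the
alleles are flagged as random monoallelic expression — the signature of
X-inactivation or transcriptional bursting, which are indistinguishable at
this level.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SNVKey
from .matrix import CellSNVMatrix, SNVProfile, all_profiles


class OriginLabel(enum.Enum):
    GERMLINE_HOM = "germline_hom"
    GERMLINE_HET = "germline_het"
    SOMATIC_LIKE = "somatic_like"
    RNA_ORIGIN_LIKE = "rna_origin_like"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class OriginThresholds:
    """Numeric thresholds parameterizing the origin rules.

    Defaults are this package's operational choices; the underlying patterns
    are qualitative.  All fractions are of covered cells unless noted.
    """

    min_cells_covered: int = 10  #: below this, the SNV stays unclassified
    hom_varonly_frac: float = 0.95  #: hom: fraction of covered cells that are var-only
    hom_mean_vaf: float = 0.95  #: hom: mean VAF over covered cells
    het_biallelic_frac: float = 0.2  #: het: fraction of covered cells biallelic
    het_median_vaf_lo: float = 0.35  #: het: median VAF band (covered cells)
    het_median_vaf_hi: float = 0.65
    somatic_cellfrac_lo: float = 0.05  #: somatic: carrier-cell fraction band
    somatic_cellfrac_hi: float = 0.5
    somatic_median_vaf: float = 0.2  #: somatic: median VAF among carrier cells
    rna_median_vaf: float = 0.2  #: rna: median VAF (covered cells) below this
    rna_median_nvar: float = 2  #: rna: median N_VAR among carriers at most this
    mono_ratio_band: tuple[float, float] = (1 / 3, 3.0)  #: var-only / ref-only cell ratio
    mono_biallelic_max_frac: float = 0.1  #: monoallelic flag: max biallelic fraction

    def __post_init__(self) -> None:
        for name in ("hom_varonly_frac", "hom_mean_vaf", "het_biallelic_frac", "mono_biallelic_max_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for lo, hi, what in (
            (self.het_median_vaf_lo, self.het_median_vaf_hi, "het_median_vaf"),
            (self.somatic_cellfrac_lo, self.somatic_cellfrac_hi, "somatic_cellfrac"),
            self.mono_ratio_band + ("mono_ratio_band",),
        ):
            if not lo < hi:
                raise ValueError(f"{what}: lower bound {lo} must be < upper bound {hi}")


@dataclass
class OriginCall:
    """Origin label plus the evidence values the rules consumed."""

    snv: SNVKey
    label: OriginLabel
    monoallelic_random_flag: bool | None  # None when coverage is insufficient
    evidence: dict = field(default_factory=dict)


def _evidence(p: SNVProfile) -> dict:
    cov = p.n_cells_covered
    return {
        "n_cells_covered": cov,
        "n_ref_only": p.n_ref_only,
        "n_var_only": p.n_var_only,
        "n_biallelic": p.n_biallelic,
        "varonly_frac": p.n_var_only / cov if cov else math.nan,
        "biallelic_frac": p.n_biallelic / cov if cov else math.nan,
        "carrier_frac": p.n_carriers / cov if cov else math.nan,
        "mean_vaf_covered": p.mean_vaf_covered,
        "median_vaf_covered": p.median_vaf_covered,
        "median_vaf_carriers": p.median_vaf_carriers,
        "median_nvar_expressing": p.median_nvar_expressing,
    }


def classify_origin(profile: SNVProfile, thresholds: OriginThresholds | None = None) -> OriginCall:
    """Assign the probable origin label for one SNV.

    Rules run in fixed order (hom -> het -> somatic -> rna); the first match
    wins, and a profile covered in fewer than ``min_cells_covered`` cells is
    left unclassified regardless of its other values.
    """
    t = thresholds or OriginThresholds()
    ev = _evidence(profile)
    flag = detect_random_monoallelic(profile, t)[0] if profile.n_cells_covered >= t.min_cells_covered else None
    if profile.n_cells_covered < t.min_cells_covered:
        return OriginCall(profile.snv, OriginLabel.UNCLASSIFIED, flag, ev)
    label = OriginLabel.UNCLASSIFIED
    if ev["varonly_frac"] >= t.hom_varonly_frac and ev["mean_vaf_covered"] >= t.hom_mean_vaf:
        label = OriginLabel.GERMLINE_HOM
    elif ev["biallelic_frac"] >= t.het_biallelic_frac and t.het_median_vaf_lo <= ev["median_vaf_covered"] <= t.het_median_vaf_hi:
        label = OriginLabel.GERMLINE_HET
    elif (
        t.somatic_cellfrac_lo <= ev["carrier_frac"] <= t.somatic_cellfrac_hi
        and ev["median_vaf_carriers"] >= t.somatic_median_vaf
    ):
        label = OriginLabel.SOMATIC_LIKE
    elif ev["median_vaf_covered"] < t.rna_median_vaf and ev["median_nvar_expressing"] <= t.rna_median_nvar:
        label = OriginLabel.RNA_ORIGIN_LIKE
    return OriginCall(profile.snv, label, flag, ev)


def detect_random_monoallelic(
    profile: SNVProfile, thresholds: OriginThresholds | None = None
) -> tuple[bool | None, dict]:
    """Flag per-cell exclusive single-allele expression split between alleles.

    True iff biallelic cells are at most ``mono_biallelic_max_frac`` of the
    covered cells and the var-only/ref-only cell ratio lies within
    ``mono_ratio_band`` (both tallies >= 1).  Returns None (undefined, not
    False) when coverage is below ``min_cells_covered``.
    """
    t = thresholds or OriginThresholds()
    ev = _evidence(profile)
    if profile.n_cells_covered < t.min_cells_covered:
        ev["reason"] = "insufficient coverage"
        return None, ev
    lo, hi = t.mono_ratio_band
    if profile.n_var_only < 1 or profile.n_ref_only < 1:
        return False, ev
    ratio = profile.n_var_only / profile.n_ref_only
    ev["varonly_refonly_ratio"] = ratio
    flag = ev["biallelic_frac"] <= t.mono_biallelic_max_frac and lo <= ratio <= hi
    return bool(flag), ev


def classify_all(m: CellSNVMatrix, thresholds: OriginThresholds | None = None) -> pd.DataFrame:
    """Classify every SNV of a matrix; one row per SNV with label, flag, evidence."""
    t = thresholds or OriginThresholds()
    rows = []
    for p in all_profiles(m):
        call = classify_origin(p, t)
        rows.append({"snv": str(call.snv), "label": call.label.value, "monoallelic_random": call.monoallelic_random_flag, **call.evidence})
    columns = ["snv", "label", "monoallelic_random", *_evidence(SNVProfile(
        SNVKey("1", 1, "A", "C"), 0, 0, 0, 0, np.empty(0), math.nan, math.nan)).keys()]
    return pd.DataFrame(rows, columns=columns)
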