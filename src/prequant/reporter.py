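"""Reporter statistics for the miniwhite eye-pigment assay.

The miniwhite (mw) reporter is dosage sensitive: eye pigment, expressed
as a percentage of wild-type pigment, reads out reporter activity. At a
fixed genomic landing site, comparing a PRE-carrying construct with the
no-PRE control at the same site, in heterozygotes and homozygotes and
in wild-type versus Polycomb-mutant backgrounds, yields four derived
statistics:

* repression index w = no-PRE pigment / PRE pigment (same site and
  zygosity); > 1 means net repression, < 1 net activation;
* pairing-sensitive silencing (PSS) score = (het/hom pigment of the PRE
  line) normalized to the same ratio for the no-PRE control at the same
  site; > 1 means silencing strengthens on transgene pairing;
* pairing-sensitive activation (PSA) = (hom/het pigment of the no-PRE
  control) / 2; the pure copy-number expectation for two reporter
  copies is a twofold pigment increase, so 1 is the null and > 1 means
  the paired locus is activated beyond gene dosage;
* Pc-mutant derepression = pigment in the Polycomb-mutant background /
  pigment in the wild-type background; > 1 diagnoses Polycomb-dependent
  silencing.

All ratios are computed from group mean pigment levels. Denominators
are floored at a configurable small pigment value and flagged censored
instead of producing infinities (homozygotes of strong PREs can be
phenotypically white). Replicate standard deviations are propagated to
first-order delta-method standard errors, labelled approximate.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections.abc import Iterable, Sequence
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: Default denominator floor, in % of wild-type pigment.
DEFAULT_FLOOR = 0.1

ZYGOSITIES = ("het", "hom")
BACKGROUNDS = ("wildtype", "Pc_mutant")

PIGMENT_COLUMNS = [
    "construct", "site", "zygosity", "background",
    "replicate", "n_heads", "pigment_pct",
]


@dataclasses.dataclass(frozen=True)
class PigmentMeasurement:
    """One replicate pigment measurement for one transgenic line."""

    construct: str
    site: str
    zygosity: str
    background: str
    replicate: int
    n_heads: int
    pigment_pct: float

    def __post_init__(self) -> None:
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"invalid zygosity {self.zygosity!r}")
        if self.background not in BACKGROUNDS:
            raise ValueError(f"invalid background {self.background!r}")
        if self.pigment_pct < 0:
            raise ValueError("pigment_pct must be >= 0")
        if self.n_heads < 1:
            raise ValueError("n_heads must be >= 1")

    @property
    def key(self) -> tuple:
        return (
            self.construct, self.site, self.zygosity,
            self.background, self.replicate,
        )


@dataclasses.dataclass(frozen=True)
class LineSummary:
    """Per-line mean and sample SD of replicate pigment values."""

    construct: str
    site: str
    zygosity: str
    background: str
    mean: float
    sd: float
    n: int
    single_replicate: bool = False

    def __post_init__(self) -> None:
        if self.mean < 0 or self.sd < 0 or self.n < 1:
            raise ValueError("invalid LineSummary")

    @property
    def group(self) -> tuple:
        return (self.construct, self.site, self.zygosity, self.background)


@dataclasses.dataclass(frozen=True)
class RepressionIndex:
    construct: str
    site: str
    zygosity: str
    value: float
    censored: bool = False
    approx_se: float | None = None


@dataclasses.dataclass(frozen=True)
class PSSScore:
    construct: str
    site: str
    value: float
    censored: bool = False
    approx_se: float | None = None


@dataclasses.dataclass(frozen=True)
class PSAScore:
    site: str
    value: float


@dataclasses.dataclass(frozen=True)
class RangeSummary:
    construct: str
    zygosity: str
    min: float
    max: float
    mean: float
    n_excluded_censored: int = 0

    def __post_init__(self) -> None:
        if not (self.min <= self.mean <= self.max):
            raise ValueError("require min <= mean <= max")


class PigmentTableError(ValueError):
    pass


def read_pigment_table(path: str | Path) -> list[PigmentMeasurement]:
    """Read a delimited pigment table and validate it.

    Required columns: construct, site, zygosity, background, replicate,
    n_heads, pigment_pct. Duplicate (construct, site, zygosity,
    background, replicate) keys and negative pigment values are
    rejected with errors naming the offence.
    """
    df = pd.read_csv(path, sep="\t", dtype={"site": str})
    missing = set(PIGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise PigmentTableError(
            f"pigment table missing column(s): {sorted(missing)}"
        )
    measurements = []
    seen = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        if row.pigment_pct < 0:
            raise PigmentTableError(
                f"line {idx}: negative pigment_pct {row.pigment_pct}"
            )
        m = PigmentMeasurement(
            construct=str(row.construct),
            site=str(row.site),
            zygosity=str(row.zygosity),
            background=str(row.background),
            replicate=int(row.replicate),
            n_heads=int(row.n_heads),
            pigment_pct=float(row.pigment_pct),
        )
        if m.key in seen:
            raise PigmentTableError(f"line {idx}: duplicate key {m.key}")
        seen.add(m.key)
        measurements.append(m)
    return measurements


def write_pigment_table(
    measurements: Iterable[PigmentMeasurement], path: str | Path
) -> None:
    df = pd.DataFrame([dataclasses.asdict(m) for m in measurements])
    df = df[PIGMENT_COLUMNS] if len(df) else pd.DataFrame(columns=PIGMENT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def summarize_lines(
    measurements: Sequence[PigmentMeasurement],
) -> list[LineSummary]:
    """Per-group arithmetic mean and sample SD (n-1 denominator).

    Single-replicate groups get sd 0 and are flagged.
    """
    if not measurements:
        raise ValueError("no measurements to summarize")
    groups: dict[tuple, list[float]] = {}
    for m in measurements:
        groups.setdefault(
            (m.construct, m.site, m.zygosity, m.background), []
        ).append(m.pigment_pct)
    summaries = []
    for key in sorted(groups):
        values = groups[key]
        n = len(values)
        mean = sum(values) / n
        if n == 1:
            sd, single = 0.0, True
        else:
            sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
            single = False
        summaries.append(
            LineSummary(*key, mean=mean, sd=sd, n=n, single_replicate=single)
        )
    return summaries


def _floored(summary: LineSummary, floor: float) -> tuple[float, bool]:
    if summary.mean < floor:
        logger.warning(
            "flooring mean pigment %.4g -> %.4g for %s",
            summary.mean, floor, summary.group,
        )
        return floor, True
    return summary.mean, False


def _rel_var(summary: LineSummary, mean_used: float) -> float:
    """First-order relative variance of a group mean."""
    if mean_used <= 0:
        return 0.0
    return (summary.sd ** 2) / (summary.n * mean_used ** 2)


def repression_index(
    ctrl: LineSummary, pre: LineSummary, floor: float = DEFAULT_FLOOR
) -> RepressionIndex:
    """Repression index w = control mean / PRE mean (same site, zygosity)."""
    if (ctrl.site, ctrl.zygosity, ctrl.background) != (
        pre.site, pre.zygosity, pre.background
    ):
        raise ValueError(
            f"group mismatch: control {ctrl.group} vs PRE {pre.group}"
        )
    denom, censored = _floored(pre, floor)
    value = ctrl.mean / denom
    se = value * math.sqrt(_rel_var(ctrl, ctrl.mean) + _rel_var(pre, denom))
    return RepressionIndex(
        construct=pre.construct,
        site=pre.site,
        zygosity=pre.zygosity,
        value=value,
        censored=censored,
        approx_se=se,
    )


def pss_score(
    pre_het: LineSummary,
    pre_hom: LineSummary,
    ctrl_het: LineSummary,
    ctrl_hom: LineSummary,
    floor: float = DEFAULT_FLOOR,
) -> PSSScore:
    """Pairing-sensitive silencing score.

    (het/hom pigment ratio of the PRE line) / (het/hom ratio of the
    no-PRE control at the same landing site). Values > 1 indicate PSS.
    """
    sites = {s.site for s in (pre_het, pre_hom, ctrl_het, ctrl_hom)}
    bgs = {s.background for s in (pre_het, pre_hom, ctrl_het, ctrl_hom)}
    if len(sites) != 1 or len(bgs) != 1:
        raise ValueError("PSS inputs must share one site and one background")
    if (pre_het.zygosity, pre_hom.zygosity) != ("het", "hom") or (
        ctrl_het.zygosity, ctrl_hom.zygosity
    ) != ("het", "hom"):
        raise ValueError("PSS inputs must be (het, hom, het, hom) as labeled")
    pre_hom_mean, c1 = _floored(pre_hom, floor)
    ctrl_hom_mean, c2 = _floored(ctrl_hom, floor)
    pre_ratio = pre_het.mean / pre_hom_mean
    ctrl_ratio = ctrl_het.mean / ctrl_hom_mean
    value = pre_ratio / ctrl_ratio
    rel = (
        _rel_var(pre_het, pre_het.mean)
        + _rel_var(pre_hom, pre_hom_mean)
        + _rel_var(ctrl_het, ctrl_het.mean)
        + _rel_var(ctrl_hom, ctrl_hom_mean)
    )
    return PSSScore(
        construct=pre_het.construct,
        site=pre_het.site,
        value=value,
        censored=c1 or c2,
        approx_se=value * math.sqrt(rel),
    )


def psa_score(ctrl_het: LineSummary, ctrl_hom: LineSummary) -> PSAScore:
    """Pairing-sensitive activation of the no-PRE control at one site.

    (hom mean / het mean) / 2, so that the pure copy-number expectation
    (two reporter copies give twice the pigment) maps to 1.
    """
    if ctrl_het.site != ctrl_hom.site or ctrl_het.construct != ctrl_hom.construct:
        raise ValueError("PSA inputs must be the same control line at one site")
    if (ctrl_het.zygosity, ctrl_hom.zygosity) != ("het", "hom"):
        raise ValueError("PSA inputs must be (het, hom) as labeled")
    if ctrl_het.mean == 0:
        raise ValueError("PSA undefined for zero heterozygote pigment")
    return PSAScore(
        site=ctrl_het.site, value=(ctrl_hom.mean / ctrl_het.mean) / 2.0
    )


def range_summary(indices: Sequence[RepressionIndex]) -> RangeSummary:
    """Min/max/mean of repression indices across landing sites.

    Censored indices are excluded and counted; an empty remainder is an
    error.
    """
    if not indices:
        raise ValueError("no repression indices")
    constructs = {i.construct for i in indices}
    zygosities = {i.zygosity for i in indices}
    if len(constructs) != 1 or len(zygosities) != 1:
        raise ValueError("range summary requires one construct and one zygosity")
    kept = [i.value for i in indices if not i.censored]
    n_excl = len(indices) - len(kept)
    if not kept:
        raise ValueError("all repression indices censored; nothing to summarize")
    return RangeSummary(
        construct=constructs.pop(),
        zygosity=zygosities.pop(),
        min=min(kept),
        max=max(kept),
        mean=sum(kept) / len(kept),
        n_excluded_censored=n_excl,
    )


def pc_derepression(
    wt: LineSummary, pc: LineSummary, floor: float = DEFAULT_FLOOR
) -> RepressionIndex:
    """Fold derepression in a Polycomb-mutant background.

    pc mean / wild-type mean for the same construct, site and zygosity;
    > 1 indicates Polycomb-dependent silencing was relieved. Returned
    as a :class:`RepressionIndex`-shaped record (value, censored flag,
    approximate SE).
    """
    if (wt.construct, wt.site, wt.zygosity) != (pc.construct, pc.site, pc.zygosity):
        raise ValueError(f"group mismatch: {wt.group} vs {pc.group}")
    if (wt.background, pc.background) != ("wildtype", "Pc_mutant"):
        raise ValueError("inputs must be (wildtype, Pc_mutant) as labeled")
    denom, censored = _floored(wt, floor)
    value = pc.mean / denom
    se = value * math.sqrt(_rel_var(pc, pc.mean) + _rel_var(wt, denom))
    return RepressionIndex(
        construct=wt.construct,
        site=wt.site,
        zygosity=wt.zygosity,
        value=value,
        censored=censored,
        approx_se=se,
    )


def compute_report(
    measurements: Sequence[PigmentMeasurement],
    control: str = "noPRE",
    floor: float = DEFAULT_FLOOR,
) -> dict[str, pd.DataFrame]:
    """Full per-dataset report: summaries, repression indices, PSS, PSA,
    Pc derepression — each as a DataFrame keyed by statistic name."""
    summaries = summarize_lines(measurements)
    by_group = {s.group: s for s in summaries}
    sites = sorted({s.site for s in summaries})
    constructs = sorted({s.construct for s in summaries})

    sum_df = pd.DataFrame([dataclasses.asdict(s) for s in summaries])

    ri_rows, pss_rows, psa_rows, pc_rows = [], [], [], []
    for site in sites:
        ctrl_het = by_group.get((control, site, "het", "wildtype"))
        ctrl_hom = by_group.get((control, site, "hom", "wildtype"))
        if ctrl_het and ctrl_hom:
            psa_rows.append(dataclasses.asdict(psa_score(ctrl_het, ctrl_hom)))
        for construct in constructs:
            if construct == control:
                continue
            pre_het = by_group.get((construct, site, "het", "wildtype"))
            pre_hom = by_group.get((construct, site, "hom", "wildtype"))
            for zyg, ctrl_s, pre_s in (
                ("het", ctrl_het, pre_het), ("hom", ctrl_hom, pre_hom)
            ):
                if ctrl_s and pre_s:
                    ri_rows.append(
                        dataclasses.asdict(
                            repression_index(ctrl_s, pre_s, floor=floor)
                        )
                    )
            if ctrl_het and ctrl_hom and pre_het and pre_hom:
                pss_rows.append(
                    dataclasses.asdict(
                        pss_score(pre_het, pre_hom, ctrl_het, ctrl_hom, floor=floor)
                    )
                )
        for construct in constructs:
            for zyg in ZYGOSITIES:
                wt = by_group.get((construct, site, zyg, "wildtype"))
                pc = by_group.get((construct, site, zyg, "Pc_mutant"))
                if wt and pc:
                    row = dataclasses.asdict(pc_derepression(wt, pc, floor=floor))
                    pc_rows.append(row)
    return {
        "line_summaries": sum_df,
        "repression_index": pd.DataFrame(ri_rows),
        "pss": pd.DataFrame(pss_rows),
        "psa": pd.DataFrame(psa_rows),
        "pc_derepression": pd.DataFrame(pc_rows),
    }
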