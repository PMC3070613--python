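"""Synthetic-data generators emulating the PRE reporter study design.

Two generators make every pipeline stage testable at desk scale:

* a pigment-assay generator with an explicit multiplicative model —
  landing-site effect, reporter copy number, pairing activation,
  PRE repression, Polycomb-mutant relief, and log-normal noise — whose
  parameters are exactly the quantities the reporter statistics
  estimate, so parameter recovery is checkable in closed form;
* a sequence generator producing GC-controlled random backgrounds with
  motifs planted at known positions (a truth channel for the scanner
  and score track).

The module also ships two small packaged sequences: a synthetic
surrogate for the 106 bp essential region at the start of the 1.6 kb
vestigial (vg) PRE. The published sequence of that region exists only
as a figure image; the surrogate reproduces its motif anatomy (one
GAGAG site, four GTGT repeat blocks in 106 bp) and embeds the printed
cloning/mutagenesis primer sequences so that the whole construct series
can be rebuilt on it in silico. It is clearly labelled synthetic and
must not be mistaken for the genomic sequence.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from importlib import resources

import numpy as np

from . import motifs as _motifs
from .constructs import ConstructSpec, PrimerRecord, read_primer_table
from .seqio import Interval, SequenceRecord, read_fasta

#: Generator version; bump when the sampling scheme changes, because
#: bit-reproducibility of seeded output is part of the contract.
GENERATOR_VERSION = "1"

CONTROL_CONSTRUCT = "noPRE"
SITES = ("1", "2", "3", "4")


@dataclasses.dataclass
class GenerativeParams:
    """Parameters of the multiplicative pigment model.

    pigment(construct c, site i, zygosity z, background b) =
        baseline * site_effect[i]
        * copy_number_factor            (hom only)
        * pairing_activation[i]         (hom only)
        * repression_factor[c, i, z]
        * pc_relief[c]                  (Pc_mutant background, hom only)
        * exp(eps),  eps ~ Normal(0, noise_sigma^2)
    capped at ``saturation_cap``.

    Units: pigment is % of wild-type, so ``baseline`` is 100 and
    ``site_effect`` is the heterozygous no-PRE pigment fraction at each
    landing site. ``copy_number_factor`` is the intrinsic hom/het dosage
    ratio (null value 2: two reporter copies, twice the pigment).
    ``pairing_activation`` multiplies homozygotes only and equals the
    PSA score the pipeline should recover; ``repression_factor`` is in
    (0, 1] with repression index = 1/repression_factor; ``pc_relief``
    >= 1 is the fold derepression of homozygous PRE lines in a
    Polycomb-mutant background.
    """

    site_effect: dict[str, float]
    pairing_activation: dict[str, float]
    repression_factor: dict[tuple[str, str, str], float]
    pc_relief: dict[str, float]
    baseline: float = 100.0
    copy_number_factor: float = 2.0
    noise_sigma: float = 0.2
    saturation_cap: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline", "copy_number_factor", "saturation_cap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for mapping in (self.site_effect, self.pairing_activation,
                        self.repression_factor, self.pc_relief):
            for key, value in mapping.items():
                if value <= 0:
                    raise ValueError(f"non-positive effect for {key!r}")


def default_params(seed: int = 0, noise_sigma: float = 0.2) -> GenerativeParams:
    """Parameter regime shaped like the published reporter data.

    Heterozygous no-PRE pigment sits in the 5-8% range (the one printed
    control value is 7% at site 4); pairing activation spans the
    reported two- to six-fold beyond dosage at sites 1-3 and is absent
    at site 4; Fab-7 repression factors span its reported 3.5-fold
    repression to 1.5-fold activation range in heterozygotes and
    18-fold repression to 1.2-fold activation in homozygotes; vg spans
    mild uniform heterozygous repression and 49- to 2.3-fold
    homozygous repression, strongest at site 3.
    """
    site_effect = {"1": 0.06, "2": 0.08, "3": 0.05, "4": 0.07}
    pairing_activation = {"1": 3.0, "2": 5.0, "3": 2.0, "4": 1.0}
    repression = {}
    for site in SITES:
        for zyg in ("het", "hom"):
            repression[(CONTROL_CONSTRUCT, site, zyg)] = 1.0
    fab7_het = {"1": 1 / 3.5, "2": 0.4, "3": 0.5, "4": 1.5}
    fab7_hom = {"1": 1 / 18, "2": 0.1, "3": 0.5, "4": 1.2}
    vg_het = {"1": 0.60, "2": 0.65, "3": 0.70, "4": 0.75}
    vg_hom = {"1": 0.10, "2": 0.05, "3": 1 / 49, "4": 1 / 2.3}
    for site in SITES:
        repression[("Fab7", site, "het")] = fab7_het[site]
        repression[("Fab7", site, "hom")] = fab7_hom[site]
        repression[("vg", site, "het")] = vg_het[site]
        repression[("vg", site, "hom")] = vg_hom[site]
    pc_relief = {CONTROL_CONSTRUCT: 1.0, "Fab7": 5.0, "vg": 10.0}
    return GenerativeParams(
        site_effect=site_effect,
        pairing_activation=pairing_activation,
        repression_factor=repression,
        pc_relief=pc_relief,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def generate_pigment_dataset(
    params: GenerativeParams,
    constructs: Sequence[str],
    sites: Sequence[str],
    n_replicates: int,
    backgrounds: Sequence[str] = ("wildtype",),
    n_heads: int = 50,
):
    """Seeded pigment measurements from the multiplicative model.

    Identical parameters and seed give a bit-identical dataset. Raises
    ``KeyError`` for a construct/site missing from the parameter maps.
    """
    from .reporter import PigmentMeasurement

    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(params.seed)
    out = []
    for construct in constructs:
        for site in sites:
            if site not in params.site_effect:
                raise KeyError(f"unknown site {site!r} in site_effect")
            for zygosity in ("het", "hom"):
                key = (construct, site, zygosity)
                if key not in params.repression_factor:
                    raise KeyError(
                        f"unknown construct/site key {key!r} in "
                        f"repression_factor"
                    )
                for background in backgrounds:
                    for replicate in range(1, n_replicates + 1):
                        value = params.baseline * params.site_effect[site]
                        if zygosity == "hom":
                            value *= params.copy_number_factor
                            value *= params.pairing_activation[site]
                        value *= params.repression_factor[key]
                        if background == "Pc_mutant" and zygosity == "hom":
                            value *= params.pc_relief[construct]
                        if params.noise_sigma > 0:
                            value *= float(
                                np.exp(rng.normal(0.0, params.noise_sigma))
                            )
                        value = min(value, params.saturation_cap)
                        out.append(
                            PigmentMeasurement(
                                construct=construct,
                                site=site,
                                zygosity=zygosity,
                                background=background,
                                replicate=replicate,
                                n_heads=n_heads,
                                pigment_pct=value,
                            )
                        )
    return out


@dataclasses.dataclass(frozen=True)
class Planting:
    """A motif text to insert, at a fixed or random position."""

    motif_name: str
    text: str
    position: int | None = None


@dataclasses.dataclass(frozen=True)
class PlantedMotifTruth:
    """Ground-truth location of one planted motif."""

    motif_name: str
    interval: Interval
    text: str


def generate_pre_sequence(
    length: int,
    background_gc: float,
    plantings: Sequence[Planting],
    seed: int,
    exclude_motifs: Iterable[_motifs.MotifModel] | None = None,
    seq_id: str = "synthetic_pre",
    max_rounds: int = 200,
) -> tuple[SequenceRecord, list[PlantedMotifTruth]]:
    """A GC-controlled random background with motifs planted at known spots.

    With ``exclude_motifs`` the background is rejection-sampled until it
    contains no occurrence of those motifs (both strands) before
    planting; bases at planted positions are then overwritten, so the
    truth list is exact for the planted copies. Planted texts may abut
    background and create additional incidental matches at their edges;
    scanner tests therefore assert containment of the truth, not
    equality.
    """
    if not (0.0 < background_gc < 1.0):
        raise ValueError("background_gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    probs = [
        (1 - background_gc) / 2, background_gc / 2,
        background_gc / 2, (1 - background_gc) / 2,
    ]
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=length, p=probs)

    if exclude_motifs:
        exclude = list(exclude_motifs)
        for _ in range(max_rounds):
            rec = SequenceRecord(id=seq_id, seq="".join(seq))
            hits = _motifs.scan_motifs(rec, exclude)
            if not hits:
                break
            for h in hits:
                iv = h.interval
                seq[iv.start:iv.end] = rng.choice(
                    bases, size=iv.end - iv.start, p=probs
                )
        else:
            raise RuntimeError(
                f"could not purge excluded motifs in {max_rounds} rounds"
            )

    placed: list[tuple[int, Planting]] = []

    def overlaps_any(start: int, end: int) -> bool:
        return any(start < e and s < end for s, e in
                   ((p, p + len(pl.text)) for p, pl in placed))

    fixed = [p for p in plantings if p.position is not None]
    random_ones = [p for p in plantings if p.position is None]
    for planting in fixed:
        start = planting.position
        if not (0 <= start and start + len(planting.text) <= length):
            raise ValueError(
                f"planting {planting.motif_name!r} at {start} exceeds "
                f"sequence length {length}"
            )
        if overlaps_any(start, start + len(planting.text)):
            raise ValueError(
                f"planting {planting.motif_name!r} at {start} overlaps "
                f"another planting"
            )
        placed.append((start, planting))
    for planting in random_ones:
        span = len(planting.text)
        if span > length:
            raise ValueError("planting longer than sequence")
        for _ in range(1000):
            start = int(rng.integers(0, length - span + 1))
            if not overlaps_any(start, start + span):
                placed.append((start, planting))
                break
        else:
            raise RuntimeError("could not place planting without overlap")

    truths = []
    for start, planting in sorted(placed):
        text = planting.text.upper()
        seq[start:start + len(text)] = list(text)
        truths.append(
            PlantedMotifTruth(
                motif_name=planting.motif_name,
                interval=Interval(seq_id, start, start + len(text)),
                text=text,
            )
        )
    return SequenceRecord(id=seq_id, seq="".join(seq)), truths


def generate_deletion_series(
    base: SequenceRecord, breakpoints: Iterable[int]
) -> list[ConstructSpec]:
    """5' truncation series of a base fragment, named systematically.

    Each breakpoint b yields a construct missing the first b bases
    (b = 0 is the identity construct, b = len(base) an empty,
    control-like product).
    """
    specs = []
    for bp in breakpoints:
        if not (0 <= bp <= len(base)):
            raise ValueError(
                f"breakpoint {bp} out of range for {base.id!r} "
                f"(length {len(base)})"
            )
        name = f"{base.id}_del5p{bp}"
        specs.append(
            ConstructSpec(
                name=name,
                template_id=base.id,
                edit_type="prefix_deletion",
                product=SequenceRecord(
                    id=name,
                    seq=base.seq[bp:],
                    description=f"5' deletion of first {bp} bp of {base.id}",
                ),
                deletion_start=0,
                deletion_end=bp,
                deleted_seq=base.seq[:bp],
            )
        )
    return specs


def _packaged(name: str):
    return resources.files("prequant").joinpath("data", name)


def build_fig5a_fixture() -> SequenceRecord:
    """The packaged 106 bp synthetic surrogate of the essential vg PRE region.

    One GAGAG (GAF/PSQ) site and four GTGT repeat blocks in 106 bp; the
    printed mutagenesis primers of the deletion series find their
    junctions on it (see module docstring). The record id and
    description mark it as synthetic.
    """
    with resources.as_file(_packaged("vg_pre_106bp_synthetic.fa")) as path:
        return read_fasta(path)[0]


def load_pre_region_template() -> SequenceRecord:
    """The 106 bp surrogate plus downstream primer-annealing context (156 bp)."""
    with resources.as_file(_packaged("vg_pre_region_synthetic.fa")) as path:
        return read_fasta(path)[0]


def load_packaged_primers() -> list[PrimerRecord]:
    """The cloning and mutagenesis primers of the reporter construct series."""
    with resources.as_file(_packaged("primers.tsv")) as path:
        return read_primer_table(path)


def get_primer(
    primers: Sequence[PrimerRecord], name: str, direction: str
) -> PrimerRecord:
    for p in primers:
        if p.name == name and p.direction == direction:
            return p
    raise KeyError(f"no primer {name!r} ({direction})")
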