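"""Study dataset container: samples, treatment pairings and stability data.

A study dataset links each raw waste to its treatment products (solid
digestate, compost, compost of digestate) and to the measured stability
response C_nm where an incubation was run.  Sample families — a waste plus
everything derived from it — are parsed from the naming convention
``<family>[-D[n]][-C[n]]`` (e.g. ``Manure1-D-C`` belongs to family
``Manure1``), and are the unit of holdout splitting so that no information
about a validation waste leaks into training.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .characterize import SampleRecord

__all__ = ["TreatmentPair", "StudyDataset", "parse_family"]


def parse_family(sample_id: str) -> str:
    """Family id: the leading token before the first treatment suffix."""
    return sample_id.split("-")[0]


@dataclass(frozen=True)
class TreatmentPair:
    """One input→product link with the process duration that produced it."""

    input_id: str
    output_id: str
    duration_days: float

    def __post_init__(self) -> None:
        if self.duration_days < 0:
            raise ValueError(
                f"pair {self.input_id}->{self.output_id}: negative duration"
            )


@dataclass
class StudyDataset:
    """All samples of a study plus the structure connecting them."""

    samples: dict[str, SampleRecord] = field(default_factory=dict)
    ad_pairs: list[TreatmentPair] = field(default_factory=list)
    compost_pairs: list[TreatmentPair] = field(default_factory=list)
    cnm: dict[str, float] = field(default_factory=dict)

    def add(self, record: SampleRecord, cnm: float | None = None) -> None:
        if record.sample_id in self.samples:
            raise ValueError(f"duplicate sample id {record.sample_id!r}")
        self.samples[record.sample_id] = record
        if cnm is not None:
            self.cnm[record.sample_id] = float(cnm)

    def family_of(self, sample_id: str) -> str:
        return parse_family(sample_id)

    @property
    def families(self) -> set[str]:
        return {parse_family(sid) for sid in self.samples}

    def wastes(self) -> list[SampleRecord]:
        return [r for r in self.samples.values() if r.route == "raw"]

    def validate_links(self) -> None:
        """Every pair endpoint must exist; raises listing the missing ids."""
        missing = []
        for pair in self.ad_pairs + self.compost_pairs:
            for sid in (pair.input_id, pair.output_id):
                if sid not in self.samples:
                    missing.append(sid)
        if missing:
            raise ValueError(f"pairs reference unknown sample ids: {sorted(set(missing))}")

    def digestate_of(self, waste_id: str) -> list[TreatmentPair]:
        return [p for p in self.ad_pairs if p.input_id == waste_id]

    def compost_of(self, input_id: str) -> list[TreatmentPair]:
        return [p for p in self.compost_pairs if p.input_id == input_id]

    def ad_source(self, digestate_id: str) -> TreatmentPair | None:
        for p in self.ad_pairs:
            if p.output_id == digestate_id:
                return p
        return None

    def compost_source(self, compost_id: str) -> TreatmentPair | None:
        for p in self.compost_pairs:
            if p.output_id == compost_id:
                return p
        return None

    def route_of(self, sample_id: str) -> tuple[str, str, float | None, float | None]:
        """Reconstruct (root waste id, route, hrt, dc) for any sample.

        The route names the chain of treatments between the raw waste and
        this sample: ``raw``, ``AD``, ``compost`` or ``AD+compost``.
        """
        comp = self.compost_source(sample_id)
        if comp is not None:
            ad = self.ad_source(comp.input_id)
            if ad is not None:
                return ad.input_id, "AD+compost", ad.duration_days, comp.duration_days
            return comp.input_id, "compost", None, comp.duration_days
        ad = self.ad_source(sample_id)
        if ad is not None:
            return ad.input_id, "AD", ad.duration_days, None
        return sample_id, "raw", None, None
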