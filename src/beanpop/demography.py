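"""Demographic scenario templates for wild/cultivated runner-bean history.

All templates describe a wild population of constant effective size NWILD
and a cultivated population founded at a bottleneck size and expanding to
its current size, with wild-to-crop migration confined to an epoch that is
the distinguishing feature of each scenario:

* ``recent``   — migration from 3000 generations ago to the present,
* ``ancient``  — migration from 6000 to 3000 generations ago,
* ``constant`` — migration from 6000 generations ago to the present
  (from the divergence time for the domestication-centre templates).

The ``tmvb`` templates model the domestication event itself: the cultivated
clade splits from the wild one at TDOM and carries an early bidirectional
exchange during the first 2000 generations after divergence. The ``smocc``
and ``surch`` templates model sympatric wild relatives that are not the
crop's direct progenitor, so their divergence time TDIV predates
domestication and their bottleneck (NAC) reflects cultivar spreading.
``bottleneck_only`` is a single-population bottleneck-and-recovery model
for cultivars without detectable wild gene flow.

Times are in generations before present; sizes are diploid effective
sizes. Migration rates are per-generation fractions of the recipient
population replaced by migrants, with MIGWC = NMWC / NWILD when expressed
as migrant counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import msprime

#: forward-time migration epoch: (older bound, younger bound, donor, recipient, rate)
MigrationEpoch = tuple[float, float, str, str, float]

SCENARIOS = (
    "tmvb_constant",
    "tmvb_recent",
    "tmvb_ancient",
    "smocc_recent",
    "smocc_ancient",
    "smocc_constant",
    "surch_recent",
    "surch_ancient",
    "surch_constant",
    "bottleneck_only",
)

RECENT_EPOCH = (3000.0, 0.0)
ANCIENT_EPOCH = (6000.0, 3000.0)
CONSTANT_EPOCH = (6000.0, 0.0)
EARLY_EXCHANGE_SPAN = 2000.0  # bidirectional epoch after TMVB divergence


class ScenarioError(ValueError):
    pass


@dataclass
class DemographicModel:
    """A validated two-population (or single-population) scenario.

    ``migration_epochs`` are in the forward-time donor->recipient sense;
    the msprime translation converts to the backward lineage convention.
    """

    name: str
    populations: list[tuple[str, str]]  # (label, class)
    parameters: dict[str, float]
    split_time: float | None  # generations ago; None for 1-pop models
    migration_epochs: list[MigrationEpoch] = field(default_factory=list)

    def __post_init__(self) -> None:
        p = self.parameters
        for key, value in p.items():
            if key.startswith("N") and value < 2:
                raise ScenarioError(f"size {key}={value} must be >= 2")
            if key.startswith("T") and value < 0:
                raise ScenarioError(f"time {key}={value} must be >= 0")
        if "NMWC" in p and "NWILD" in p and "MIGWC" in p:
            expected = p["NMWC"] / p["NWILD"]
            if not math.isclose(p["MIGWC"], expected, rel_tol=1e-9):
                raise ScenarioError(
                    f"MIGWC={p['MIGWC']} inconsistent with NMWC/NWILD={expected}"
                )
        horizon = self.split_time if self.split_time is not None else p.get("TBOT", math.inf)
        for older, younger, donor, recipient, rate in self.migration_epochs:
            if younger < 0 or older <= younger:
                raise ScenarioError(
                    f"bad migration epoch bounds ({older}, {younger})"
                )
            if older > horizon + 1e-9:
                raise ScenarioError(
                    f"migration epoch starts at {older}, before the model's "
                    f"time horizon {horizon}"
                )
            if rate < 0:
                raise ScenarioError("negative migration rate")
            labels = {lbl for lbl, _ in self.populations}
            if donor not in labels or recipient not in labels:
                raise ScenarioError(f"unknown population in epoch {donor}->{recipient}")

    # ------------------------------------------------------------------
    def to_msprime(self) -> msprime.Demography:
        """Translate to an msprime Demography (backward-time conventions)."""
        p = self.parameters
        dem = msprime.Demography()
        if self.name == "trio":
            return self._trio_demography()
        if self.name == "bottleneck_only":
            ncur, nbot, nanc = p["NCUR"], p["NBOT"], p["NANC"]
            texp, tbot = p["TEXP"], p["TBOT"]
            growth = math.log(ncur / nbot) / texp if texp > 0 else 0.0
            dem.add_population(name="cult", initial_size=ncur, growth_rate=growth)
            dem.add_population_parameters_change(
                time=texp, population="cult", initial_size=nbot, growth_rate=0.0
            )
            dem.add_population_parameters_change(
                time=tbot, population="cult", initial_size=nanc
            )
            dem.sort_events()
            return dem

        nwild, nac, ncc = p["NWILD"], p["NAC"], p["NCC"]
        texp = p["TEXP"]
        split = float(self.split_time)
        growth = math.log(ncc / nac) / texp if texp > 0 else 0.0
        dem.add_population(name="wild", initial_size=nwild)
        dem.add_population(name="cult", initial_size=ncc, growth_rate=growth)
        dem.add_population(name="anc", initial_size=nwild)
        dem.add_population_parameters_change(
            time=texp, population="cult", initial_size=nac, growth_rate=0.0
        )
        # piecewise-constant migration per backward-ordered (source, dest) pair
        for donor, recipient in (("wild", "cult"), ("cult", "wild")):
            # backward: recipient lineages jump to donor at the forward rate
            source, dest = recipient, donor
            changes: dict[float, float] = {}
            epochs = [
                e for e in self.migration_epochs if e[2] == donor and e[3] == recipient
            ]
            for older, younger, _, _, rate in epochs:
                older = min(older, split)
                if older <= younger:
                    continue
                changes[younger] = changes.get(younger, 0.0) + rate
                changes.setdefault(older, 0.0)
            if not changes:
                continue
            rate_now = changes.pop(0.0, 0.0)
            if rate_now > 0:
                dem.set_migration_rate(source=source, dest=dest, rate=rate_now)
            for t in sorted(changes):
                dem.add_migration_rate_change(
                    time=t, source=source, dest=dest, rate=changes[t]
                )
        dem.add_population_split(
            time=split, derived=["wild", "cult"], ancestral="anc"
        )
        dem.sort_events()
        return dem


    def _trio_demography(self) -> msprime.Demography:
        """Four-taxon tree (((h1, h2), h3), out) with optional forward-time
        h3 -> h2 migration in one epoch."""
        p = self.parameters
        ne = p["NE"]
        t12, t3, t4 = p["T12"], p["T3"], p["T4"]
        dem = msprime.Demography()
        for name in ("h1", "h2", "h3", "out", "anc12", "anc123", "root"):
            dem.add_population(name=name, initial_size=ne)
        for donor, recipient in (("h3", "h2"), ("h3", "h1"), ("h2", "h3")):
            epochs = [
                e for e in self.migration_epochs
                if e[2] == donor and e[3] == recipient and e[4] > 0
            ]
            for older, younger, _, _, rate in epochs:
                older = min(older, t12)
                if older <= younger:
                    continue
                if younger == 0:
                    dem.set_migration_rate(source=recipient, dest=donor, rate=rate)
                else:
                    dem.add_migration_rate_change(
                        time=younger, source=recipient, dest=donor, rate=rate
                    )
                dem.add_migration_rate_change(
                    time=older, source=recipient, dest=donor, rate=0.0
                )
        dem.add_population_split(time=t12, derived=["h1", "h2"], ancestral="anc12")
        dem.add_population_split(time=t3, derived=["anc12", "h3"], ancestral="anc123")
        dem.add_population_split(time=t4, derived=["anc123", "out"], ancestral="root")
        dem.sort_events()
        return dem


def build_trio(
    ne: float = 10_000,
    t12: float = 4_000,
    t3: float = 10_000,
    t4: float = 30_000,
    migration_rate: float = 0.0,
    migration_epoch: tuple[float, float] = (3000.0, 0.0),
    donor: str = "h3",
    recipient: str = "h2",
) -> DemographicModel:
    """Four-taxon model (((h1, h2), h3), out) for ABBA-BABA experiments.

    ``h1``/``h2`` stand for two cultivated receptor populations, ``h3``
    for the candidate wild donor, ``out`` for the outgroup species. With
    ``migration_rate > 0`` the donor contributes migrants to the
    recipient during ``migration_epoch`` (older bound, younger bound,
    generations ago, forward-time sense).
    """
    epochs: list[MigrationEpoch] = []
    if migration_rate > 0:
        older, younger = migration_epoch
        epochs.append((min(older, t12), younger, donor, recipient, migration_rate))
    return DemographicModel(
        name="trio",
        populations=[
            ("h1", "cultivated"),
            ("h2", "cultivated"),
            ("h3", "wild"),
            ("out", "outgroup"),
        ],
        parameters={"NE": ne, "T12": t12, "T3": t3, "T4": t4},
        split_time=t3,
        migration_epochs=epochs,
    )


def build_scenario(name: str, params: dict[str, float]) -> DemographicModel:
    """Instantiate one of the named scenario templates.

    Raises :class:`ScenarioError` if a required parameter is missing or
    ordering constraints (e.g. TEXP < TDOM) are violated.
    """
    if name not in SCENARIOS:
        raise ScenarioError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    params = dict(params)

    def need(*keys: str) -> None:
        for k in keys:
            if k not in params:
                raise ScenarioError(f"scenario {name!r} requires parameter {k!r}")

    if name == "bottleneck_only":
        need("NANC", "TBOT", "NBOT", "TEXP", "NCUR")
        if params["TEXP"] >= params["TBOT"]:
            raise ScenarioError("TEXP must be younger than TBOT")
        return DemographicModel(
            name=name,
            populations=[("cult", "cultivated")],
            parameters=params,
            split_time=None,
        )

    group, timing = name.split("_")
    need("NWILD", "NAC", "NCC", "TEXP", "MIGWC")
    if group == "tmvb":
        need("TDOM")
        split = params["TDOM"]
        if params["TEXP"] > params["TDOM"]:
            raise ScenarioError("TEXP must not exceed TDOM")
    else:
        need("TDIV")
        split = params["TDIV"]
        if params["TEXP"] > params["TDIV"]:
            raise ScenarioError("TEXP must not exceed TDIV")

    m = params["MIGWC"]
    epochs: list[MigrationEpoch] = []
    if timing == "recent":
        older, younger = RECENT_EPOCH
    elif timing == "ancient":
        older, younger = ANCIENT_EPOCH
    else:  # constant
        older, younger = (split, 0.0) if group == "tmvb" else CONSTANT_EPOCH
    older = min(older, split)
    if m > 0 and older > younger:
        epochs.append((older, younger, "wild", "cult", m))

    if group == "tmvb":
        # early-domestication bidirectional exchange
        mcw = params.get("MIGCW", m)
        early_older = split
        early_younger = max(0.0, split - EARLY_EXCHANGE_SPAN)
        if mcw > 0 and early_older > early_younger:
            epochs.append((early_older, early_younger, "cult", "wild", mcw))
        if m > 0 and timing != "constant" and early_older > early_younger:
            # wild->cult leg of the early exchange (constant already covers it)
            epochs.append((early_older, early_younger, "wild", "cult", m))

    return DemographicModel(
        name=name,
        populations=[("wild", "wild"), ("cult", "cultivated")],
        parameters=params,
        split_time=split,
        migration_epochs=epochs,
    )
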