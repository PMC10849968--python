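"""Condition registry: ZT times, sleep/wake grouping and the sleep-drive template.

Experimental conditions in this kind of study carry up to three pieces of
design information per condition: the Zeitgeber time (ZT) at which the flies
were collected, whether the condition belongs to the pooled *sleep* or *wake*
group for differential expression, and an ordinal rank on the sleep-pressure
axis (from pharmacologically induced sleep, lowest pressure, to prolonged
sleep deprivation, highest).  The drive template assigns each ranked
condition an evenly spaced value in [0, 1] following that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = ["Condition", "ConditionDesign", "build_template", "default_design"]

SW_GROUPS = ("sleep", "wake", "excluded")


@dataclass(frozen=True)
class Condition:
    """One experimental condition.

    Parameters
    ----------
    name : str
        Unique condition label (e.g. ``"ZT8-Sleep"`` or ``"d3"``).
    zt : float or None
        Zeitgeber time in hours, or ``None`` if the condition is not part of
        the circadian sampling grid.
    sw_group : {"sleep", "wake", "excluded"}
        Membership in the pooled sleep or wake group.
    drive_rank : int or None
        Position on the sleep-pressure axis (0 = lowest pressure), or
        ``None`` if the condition is not drive-ranked.
    """

    name: str
    zt: Optional[float] = None
    sw_group: str = "excluded"
    drive_rank: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sw_group not in SW_GROUPS:
            raise ValueError(
                f"sw_group must be one of {SW_GROUPS}, got {self.sw_group!r}"
            )


@dataclass
class ConditionDesign:
    """Registry of all conditions in a study design."""

    conditions: list[Condition] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate condition names in design")
        ranks = [c.drive_rank for c in self.conditions if c.drive_rank is not None]
        if len(set(ranks)) != len(ranks):
            raise ValueError("duplicate drive ranks in design")

    def __getitem__(self, name: str) -> Condition:
        for c in self.conditions:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.conditions]

    @property
    def sleep_conditions(self) -> list[str]:
        return [c.name for c in self.conditions if c.sw_group == "sleep"]

    @property
    def wake_conditions(self) -> list[str]:
        return [c.name for c in self.conditions if c.sw_group == "wake"]

    @property
    def ranked_conditions(self) -> list[Condition]:
        """Drive-ranked conditions, sorted by increasing sleep pressure."""
        ranked = [c for c in self.conditions if c.drive_rank is not None]
        return sorted(ranked, key=lambda c: c.drive_rank)

    @property
    def zts(self) -> list[float]:
        """Distinct ZT values present, sorted."""
        return sorted({c.zt for c in self.conditions if c.zt is not None})

    def template(self) -> list[tuple[str, float]]:
        return build_template(self)


def build_template(design: ConditionDesign) -> list[tuple[str, float]]:
    """Sleep-drive template: evenly spaced values on [0, 1] in rank order.

    With *k* ranked conditions the i-th condition (0-based, by increasing
    sleep pressure) receives the value ``i / (k - 1)``, so the lowest-pressure
    condition maps to 0 and the highest to 1.

    Raises
    ------
    ValueError
        If fewer than two conditions are drive-ranked.
    """
    ranked = design.ranked_conditions
    k = len(ranked)
    if k < 2:
        raise ValueError(f"drive template needs >= 2 ranked conditions, got {k}")
    return [(c.name, i / (k - 1)) for i, c in enumerate(ranked)]


def default_design(
    zts: Sequence[float] = (2, 8, 14, 20),
    sleep_wake: bool = True,
    n_drive: int = 7,
) -> ConditionDesign:
    """Default condition registry.

    One sleep and one wake condition per ZT (named ``ZT{t}-Sleep`` /
    ``ZT{t}-Wake``) plus ``n_drive`` drive-ranked conditions ``d0..d{n-1}``
    ordered from lowest (d0) to highest (d{n-1}) sleep pressure.  The drive
    conditions carry no ZT and are excluded from the sleep/wake pooling;
    with ``sleep_wake=False`` each ZT gets a single sleep-group condition
    ``ZT{t}``.
    """
    conds: list[Condition] = []
    for t in zts:
        t_label = int(t) if float(t).is_integer() else t
        if sleep_wake:
            conds.append(Condition(f"ZT{t_label}-Sleep", zt=t, sw_group="sleep"))
            conds.append(Condition(f"ZT{t_label}-Wake", zt=t, sw_group="wake"))
        else:
            conds.append(Condition(f"ZT{t_label}", zt=t, sw_group="sleep"))
    for i in range(n_drive):
        conds.append(Condition(f"d{i}", sw_group="excluded", drive_rank=i))
    return ConditionDesign(conds)
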