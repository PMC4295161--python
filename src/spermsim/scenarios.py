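"""Perturbation scenarios: published presets and a generic override
mechanism.

A scenario is a list of hourly windows, each either overriding one
registered parameter (dotted path into the parameter set) or pausing the
spermatogonial compartment (stem cells and differentiating spermatogonia
fully quiescent: no timer progression, division, differentiation, death or
movement), plus an optional Stage-I initial-condition variant.

Shipped presets:

``vad``
    Vitamin-A deficiency: the preleptotene count required to license
    asymmetric stem division is raised from 5 to 50, a level the tubule
    never reaches, so spermatogonial differentiation stops and the
    developing germ cells clear over four cycles while the stem pool is
    untouched.

``stra8``
    *Stra8* loss (no meiotic entry): preleptotene differentiation is slowed
    from 44 h to 93 h, beyond the preleptotene lifespan window, so no cell
    progresses past the preleptotene/leptotene stages; the cycle itself
    keeps running because preleptotenes still appear and license stem
    divisions.  Initial condition: Stage I with spermatogonia only.

``win18446`` (and ``win18446_ra``)
    Transient chemical block of retinoic-acid synthesis: spermatogonial
    differentiation is arrested for ``arrest_days`` days starting at
    ``start_day``.  The RA-rescue variant additionally accelerates the
    division of differentiating spermatogonia from 88 h to 68 h from the
    treatment window onward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .parameters import ParameterSet

__all__ = ["ScenarioOverride", "ScenarioPreset", "preset_vad", "preset_stra8",
           "preset_win", "get_scenario", "PRESET_NAMES"]

INF = 10 ** 9


@dataclass(frozen=True)
class ScenarioOverride:
    """One override window: ``parameter_path`` is a dotted path into the
    parameter set (e.g. ``differentiation_time.preleptotene``) or the
    special key ``freeze_spermatogonia``."""

    start_hour: int
    end_hour: int | None
    parameter_path: str
    value: object

    def active(self, hour: int) -> bool:
        end = INF if self.end_hour is None else self.end_hour
        return self.start_hour <= hour < end


@dataclass
class ScenarioPreset:
    """A named scenario: override windows plus initial-condition variant."""

    name: str
    overrides: list[ScenarioOverride] = field(default_factory=list)
    initial_condition_variant: str = "normal"
    _cache_key: tuple = field(default=None, repr=False, compare=False)
    _cache_val: tuple = field(default=None, repr=False, compare=False)

    def validate(self, params: ParameterSet) -> None:
        for ov in self.overrides:
            if ov.parameter_path == "freeze_spermatogonia":
                continue
            parts = ov.parameter_path.split(".")
            obj = params
            try:
                head = getattr(obj, parts[0])
                if len(parts) == 2 and parts[1] not in head:
                    raise KeyError(parts[1])
            except (AttributeError, KeyError, TypeError):
                raise ValueError(f"override names unknown parameter "
                                 f"{ov.parameter_path!r}") from None
            if ov.end_hour is not None and ov.end_hour <= ov.start_hour:
                raise ValueError(f"override window for {ov.parameter_path!r} "
                                 f"is empty or reversed")

    def reset(self) -> None:
        self._cache_key = None
        self._cache_val = None

    def effective(self, base: ParameterSet, hour: int):
        """(parameters, spermatogonia_frozen) effective at ``hour``.

        The parameter copy is rebuilt only when the set of active windows
        changes, so per-hour application is cheap.
        """
        active = tuple(i for i, ov in enumerate(self.overrides)
                       if ov.active(hour))
        if active == self._cache_key:
            return self._cache_val
        frozen = False
        p = base
        modified = False
        for i in active:
            ov = self.overrides[i]
            if ov.parameter_path == "freeze_spermatogonia":
                frozen = bool(ov.value)
                continue
            if not modified:
                p = base.copy()
                modified = True
            parts = ov.parameter_path.split(".")
            if len(parts) == 1:
                setattr(p, parts[0], ov.value)
            else:
                getattr(p, parts[0])[parts[1]] = ov.value
        self._cache_key = active
        self._cache_val = (p, frozen)
        return self._cache_val


# ---------------------------------------------------------------------------
# Published presets
# ---------------------------------------------------------------------------


def preset_vad() -> ScenarioPreset:
    """Vitamin-A deficiency: feedback threshold 5 -> 50 from t = 0,
    normal Stage-I initial condition."""
    return ScenarioPreset("vad", [
        ScenarioOverride(0, None, "preleptotene_threshold", 50),
    ])


def preset_stra8() -> ScenarioPreset:
    """Meiotic-entry failure: preleptotene differentiation 44 h -> 93 h,
    Stage I with only stem cells and differentiating spermatogonia."""
    return ScenarioPreset("stra8", [
        ScenarioOverride(0, None, "differentiation_time.preleptotene", 93),
    ], initial_condition_variant="spermatogonia_only")


def preset_win(arrest_days: int = 8, start_day: int = 5,
               accelerate: bool = False) -> ScenarioPreset:
    """Reversible contraceptive treatment: spermatogonial arrest for
    ``arrest_days`` days from day ``start_day``; the RA-rescue variant
    also accelerates spermatogonial division from 88 h to 68 h."""
    if arrest_days < 0 or start_day < 0:
        raise ValueError("arrest_days and start_day must be non-negative")
    t0, t1 = 24 * start_day, 24 * (start_day + arrest_days)
    overrides = [ScenarioOverride(t0, t1, "freeze_spermatogonia", True)]
    name = "win18446"
    if accelerate:
        overrides.append(ScenarioOverride(t0, None,
                                          "division_time.diff_spg", 68))
        name = "win18446_ra"
    return ScenarioPreset(name, overrides)


PRESET_NAMES = ("vad", "stra8", "win18446", "win18446_ra")


def get_scenario(spec: str | None) -> ScenarioPreset | None:
    """Parse a scenario spec string, e.g. ``win18446:days=16,start=5``."""
    if spec is None or spec == "none":
        return None
    name, _, argstr = spec.partition(":")
    kwargs = {}
    if argstr:
        for part in argstr.split(","):
            key, _, val = part.partition("=")
            kwargs[key.strip()] = val.strip() or True
    if name == "vad":
        return preset_vad()
    if name == "stra8":
        return preset_stra8()
    if name in ("win18446", "win18446_ra"):
        return preset_win(
            arrest_days=int(kwargs.get("days", 8)),
            start_day=int(kwargs.get("start", 5)),
            accelerate=(name == "win18446_ra"
                        or kwargs.get("accelerate") in (True, "true", "1")))
    raise ValueError(f"unknown scenario {name!r}; "
                     f"available presets: {', '.join(PRESET_NAMES)}")
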