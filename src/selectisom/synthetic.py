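"""Synthetic compound libraries with planted selectivity structure.

The real 153-compound cathepsin K/S panel was never deposited, so end-to-end
behavior is exercised on generated libraries that reproduce its statistical
skeleton: three selectivity sets of 46 (K/S), 49 (KS) and 58 (S/K) compounds,
pIC50 values inside [3.9, 9.7], selectivity ratios >= 50 for the selective
sets and < 10 for the non-selective set, plus a decoy pool (default 1000)
without class structure.

Structures are assembled from a small fragment grammar (a versioned TSV
resource): a substituted core ring, an amide / ester / carbamate linker to a
second ring, random decorations, and per-class signature fragments —

* K/S: thiophene core (aromatic sulfur) carrying a nitrile — the electrophilic
  warhead of covalent cysteine-protease inhibitors — and a thioether,
* S/K: pyridine core (aromatic ring nitrogen) carrying an aryl chloride,
* KS: pyridine core carrying a thioether — a mix of the two selective
  signatures with no fragment exclusive to the set.

Signatures are attached to every member of their set, so signature bits have
in-set frequency 1; all other grammar choices are shared across sets and
decoys. A configurable fraction of decoys (default 1%) carries one set's
full signature and serves as recoverable ground-truth "hits".

Activities are drawn so the selectivity ratio lands in the set's range with
the correct direction and both pIC50 values respect the global bounds:
on-target pIC50 ~ Uniform[lo + log10(SR), hi], off-target = on - log10(SR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

from .fingerprints import BAPSKeyTable, Scheme, fingerprinter_for
from .markers import bit_frequencies
from .records import ActivityRecord, CompoundRecord, Source
from .selectivity import SetLabel, Target

GRAMMAR_RESOURCE = "fragment_grammar.tsv"

CLASS_ORDER = (SetLabel.K_OVER_S, SetLabel.KS_NONSELECTIVE, SetLabel.S_OVER_K)

#: core ring, list of signature substituents per selectivity set
CLASS_SIGNATURES: dict[SetLabel, tuple[str, tuple[str, ...]]] = {
    SetLabel.K_OVER_S: ("thiophene", ("nitrile", "thioether")),
    SetLabel.S_OVER_K: ("pyridine", ("chloro",)),
    SetLabel.KS_NONSELECTIVE: ("pyridine", ("thioether",)),
}

# library compounds keep a fixed (aromatic) second ring so that within-set
# structural variance stays below the between-set signature separation, the
# regime the method assumes; decoys draw their core from a wider ring pool.
_LIBRARY_RING2 = "benzene"
_DECOY_RING1_POOL = ("benzene", "cyclohexane", "furan", "thiophene")


def load_grammar() -> dict[str, dict[str, str]]:
    """Fragment grammar as {kind: {name: smiles-template}} from the TSV resource."""
    grammar: dict[str, dict[str, str]] = {}
    res = resources.files("selectisom.resources") / GRAMMAR_RESOURCE
    for line in res.read_text(encoding="utf-8").splitlines():
        if not line or line.startswith("#"):
            continue
        kind, name, smiles = (line.split("\t") + [""])[:3]
        grammar.setdefault(kind, {})[name] = smiles
    return grammar


def _fill(template: str, **slots: str) -> str:
    return template.format(**slots).replace("()", "")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic panel; defaults mirror the reference panel."""

    set_sizes: dict[SetLabel, int] = field(
        default_factory=lambda: {
            SetLabel.K_OVER_S: 46,
            SetLabel.KS_NONSELECTIVE: 49,
            SetLabel.S_OVER_K: 58,
        }
    )
    n_decoys: int = 1000
    pic50_range: tuple[float, float] = (3.9, 9.7)
    sr_selective_range: tuple[float, float] = (50.0, 250_000.0)
    sr_nonselective_range: tuple[float, float] = (1.0, 10.0)
    decoy_signature_fraction: float = 0.01
    signatures_enabled: bool = True
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.pic50_range
        if lo >= hi:
            raise ValueError("pic50_range must be increasing")
        if math.log10(self.sr_selective_range[1]) > hi - lo:
            raise ValueError(
                "sr_selective_range upper bound incompatible with pic50_range: "
                "log10(SR) must not exceed the pIC50 span"
            )
        if any(n < 0 for n in self.set_sizes.values()) or self.n_decoys < 0:
            raise ValueError("sizes must be non-negative")
        if not (0.0 <= self.decoy_signature_fraction <= 1.0):
            raise ValueError("decoy_signature_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Generation-time truth for downstream recovery checks."""

    class_of: dict[str, SetLabel]
    planted_decoys: dict[str, SetLabel]
    signatures: dict[str, tuple[str, tuple[str, ...]]]


def _assemble(
    rng: np.random.Generator,
    grammar: Mapping[str, Mapping[str, str]],
    core: str,
    signature_frags: Sequence[str],
) -> str:
    ring1 = grammar["ring1"][core]
    ring2 = _fill(grammar["ring2"][_LIBRARY_RING2], d=_pick(rng, grammar["decoration"]))
    link = _pick(rng, grammar["linker"]) + ring2
    sigs = [grammar["signature"][name] for name in signature_frags]
    s1 = sigs[0] if len(sigs) > 0 else _pick(rng, grammar["decoration"])
    s2 = sigs[1] if len(sigs) > 1 else _pick(rng, grammar["decoration"])
    return _fill(ring1, link=link, s1=s1, s2=s2)


def _pick(rng: np.random.Generator, options: Mapping[str, str]) -> str:
    names = sorted(options)
    return options[names[rng.integers(len(names))]]


def _draw_activity(
    rng: np.random.Generator,
    cid: str,
    sr_range: tuple[float, float],
    favored: Target,
    pic50_range: tuple[float, float],
) -> ActivityRecord:
    lo, hi = pic50_range
    log_sr = rng.uniform(math.log10(sr_range[0]), math.log10(sr_range[1]))
    pic_on = rng.uniform(lo + log_sr, hi)
    pic_off = pic_on - log_sr
    ic_on = 10.0 ** (9.0 - pic_on)
    ic_off = 10.0 ** (9.0 - pic_off)
    if favored is Target.K:
        return ActivityRecord(cid, ic_on, ic_off)
    return ActivityRecord(cid, ic_off, ic_on)


def generate_library(
    config: GeneratorConfig | None = None,
) -> tuple[list[CompoundRecord], list[ActivityRecord], GroundTruth]:
    """Generate the selectivity library plus decoys with recorded ground truth.

    Returns (records, activities, truth): records hold the library compounds
    first, decoys after; every compound (including decoys) has an activity
    record so selected hits can always be annotated.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    grammar = load_grammar()

    records: list[CompoundRecord] = []
    activities: list[ActivityRecord] = []
    class_of: dict[str, SetLabel] = {}

    prefixes = {
        SetLabel.K_OVER_S: "KS_sel",
        SetLabel.KS_NONSELECTIVE: "NS",
        SetLabel.S_OVER_K: "SK_sel",
    }
    for label in CLASS_ORDER:
        core, frags = CLASS_SIGNATURES[label]
        if not config.signatures_enabled:
            core, frags = "benzene", ()
        if label is SetLabel.KS_NONSELECTIVE:
            sr_range, favored_pool = config.sr_nonselective_range, (Target.K, Target.S)
        else:
            sr_range = config.sr_selective_range
            favored_pool = (Target.K,) if label is SetLabel.K_OVER_S else (Target.S,)
        for i in range(config.set_sizes.get(label, 0)):
            cid = f"{prefixes[label]}_{i + 1:03d}"
            smiles = _assemble(rng, grammar, core, frags)
            records.append(CompoundRecord(cid, smiles, Source.SELECTIVITY_DB))
            favored = favored_pool[rng.integers(len(favored_pool))]
            activities.append(
                _draw_activity(rng, cid, sr_range, favored, config.pic50_range)
            )
            class_of[cid] = label

    decoys, decoy_activities, planted = _generate_decoys(config, rng, grammar)
    records.extend(decoys)
    activities.extend(decoy_activities)

    truth = GroundTruth(
        class_of=class_of,
        planted_decoys=planted,
        signatures={label.value: CLASS_SIGNATURES[label] for label in CLASS_ORDER},
    )
    return records, activities, truth


def generate_decoys(
    config: GeneratorConfig | None = None,
) -> tuple[list[CompoundRecord], list[ActivityRecord], dict[str, SetLabel]]:
    """Decoy pool only (same grammar, no class signature except planted hits)."""
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    return _generate_decoys(config, rng, load_grammar())


def _generate_decoys(
    config: GeneratorConfig,
    rng: np.random.Generator,
    grammar: Mapping[str, Mapping[str, str]],
) -> tuple[list[CompoundRecord], list[ActivityRecord], dict[str, SetLabel]]:
    n = config.n_decoys
    n_planted = int(round(config.decoy_signature_fraction * n))
    if not config.signatures_enabled:
        n_planted = 0
    planted_idx = set(
        rng.choice(n, size=n_planted, replace=False).tolist()
    ) if n_planted else set()
    records, activities = [], []
    planted: dict[str, SetLabel] = {}
    for i in range(n):
        cid = f"Z{i + 1:05d}"
        if i in planted_idx:
            label = CLASS_ORDER[rng.integers(len(CLASS_ORDER))]
            core, frags = CLASS_SIGNATURES[label]
            planted[cid] = label
            if label is SetLabel.KS_NONSELECTIVE:
                sr_range, favored = config.sr_nonselective_range, (Target.K, Target.S)
            else:
                sr_range = config.sr_selective_range
                favored = (Target.K,) if label is SetLabel.K_OVER_S else (Target.S,)
        else:
            core = _DECOY_RING1_POOL[rng.integers(len(_DECOY_RING1_POOL))]
            frags = ()
            sr_range, favored = (1.0, 5.0), (Target.K, Target.S)
        records.append(CompoundRecord(cid, _assemble(rng, grammar, core, frags), Source.DECOY))
        activities.append(
            _draw_activity(
                rng, cid, sr_range, favored[rng.integers(len(favored))], config.pic50_range
            )
        )
    return records, activities, planted


def planted_marker_bits(
    records: Sequence[CompoundRecord],
    truth: GroundTruth,
    scheme: Scheme,
    min_in: float = 0.5,
    min_diff: float = 0.5,
    table: BAPSKeyTable | None = None,
) -> dict[str, set[int]]:
    """Ground-truth differential bits per set, from true class membership.

    Applies the marker rule (freq_in >= min_in, freq_in - freq_rest >=
    min_diff) with the true partition of the library — the reference against
    which cluster-recovered markers are scored.
    """
    transformer = fingerprinter_for(scheme, table)
    library = [r for r in records if r.source is Source.SELECTIVITY_DB]
    fps = transformer.transform([r.smiles for r in library])
    labels = np.array([truth.class_of[r.compound_id].value for r in library])
    out: dict[str, set[int]] = {}
    for label in CLASS_ORDER:
        mask = labels == label.value
        if not mask.any() or mask.all():
            out[label.value] = set()
            continue
        freq_in = bit_frequencies(fps[mask])
        freq_rest = bit_frequencies(fps[~mask])
        out[label.value] = set(
            np.flatnonzero((freq_in >= min_in) & (freq_in - freq_rest >= min_diff)).tolist()
        )
    return out
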