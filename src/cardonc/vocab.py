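"""Guideline-directed medical therapy (GDMT) drug vocabulary.

Medication classification mirrors how a formulary vocabulary (FDB-style
pharmaceutical class / subclass titles) is queried in practice:

* beta-blockers for reduced-EF cardiomyopathy are an explicit ingredient
  list — carvedilol, metoprolol SUCCINATE (not tartrate), bisoprolol;
* ACE inhibitors match any class or subclass title containing the phrase
  "ACE Inhibitor", plus a short list of combination products;
* ARBs match class titles containing "Angiotensin Receptor Antagonist",
  "Angiotensin Receptor Blocker", "Angiotensin II Receptor Blocker" or the
  abbreviation "ARB" (as a whole word, so "BARBITURATE" never matches),
  plus aliskiren/valsartan;
* MRAs match subclass titles containing "Aldosterone Receptor Antagonist".

The default title lists are synthetic stand-ins with the conventional
cardinalities (2 ACEi classes + 7 subclasses, 6 ARB classes, 2 MRA
subclasses, 8 ACEi combination products); all matching is on phrase
containment, so any vocabulary with the same phrases behaves identically.
Vocabularies are editable: ``write_vocabulary`` / ``load_vocabulary``
round-trip the file formats documented below.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["DrugVocabulary", "default_vocabulary", "load_vocabulary", "write_vocabulary"]

DEFAULT_BETA_BLOCKER_INGREDIENTS = ["carvedilol", "metoprolol succinate", "bisoprolol"]

# phrases looked for in class/subclass titles (case-insensitive containment)
ACEI_PHRASE = "ace inhibitor"
ARB_PHRASES = [
    "angiotensin receptor antagonist",
    "angiotensin receptor blocker",
    "angiotensin ii receptor blocker",
]
ARB_ABBREVIATION = "arb"  # matched on word boundaries only
MRA_PHRASE = "aldosterone receptor antagonist"

# synthetic stand-in title lists with the conventional cardinalities
DEFAULT_ACEI_CLASSES = [
    "ACE Inhibitors",
    "ACE Inhibitors & Calcium Channel Blockers",
]
DEFAULT_ACEI_SUBCLASSES = [
    "ACE Inhibitors",
    "ACE Inhibitors & Thiazide Diuretics",
    "ACE Inhibitors & Calcium Channel Blockers",
    "ACE Inhibitor-Diuretic Combinations",
    "ACE Inhibitors, Sulfhydryl",
    "ACE Inhibitors, Dicarboxylate",
    "ACE Inhibitors, Phosphonate",
]
DEFAULT_ARB_CLASSES = [
    "Angiotensin II Receptor Blockers (ARBs)",
    "Angiotensin Receptor Antagonists",
    "Angiotensin Receptor Blocker & Thiazide Diuretic",
    "ARB-Calcium Channel Blocker Combinations",
    "ARB-Neprilysin Inhibitors",
    "Angiotensin II Receptor Blocker-Diuretic Combinations",
]
DEFAULT_MRA_SUBCLASSES = [
    "Aldosterone Receptor Antagonists",
    "Aldosterone Receptor Antagonist-Diuretic Combinations",
]
DEFAULT_ACEI_COMBINATIONS = [
    "lisinopril/hydrochlorothiazide",
    "benazepril/amlodipine",
    "enalapril/hydrochlorothiazide",
    "quinapril/hydrochlorothiazide",
    "captopril/hydrochlorothiazide",
    "fosinopril/hydrochlorothiazide",
    "trandolapril/verapamil",
    "perindopril/amlodipine",
]
ARB_EXTRA_INGREDIENTS = ["aliskiren/valsartan"]


@dataclass(frozen=True)
class DrugVocabulary:
    """Ingredient and title lists driving GDMT medication classification."""

    beta_blocker_ingredients: tuple[str, ...] = tuple(DEFAULT_BETA_BLOCKER_INGREDIENTS)
    acei_classes: tuple[str, ...] = tuple(DEFAULT_ACEI_CLASSES)
    acei_subclasses: tuple[str, ...] = tuple(DEFAULT_ACEI_SUBCLASSES)
    acei_combinations: tuple[str, ...] = tuple(DEFAULT_ACEI_COMBINATIONS)
    arb_classes: tuple[str, ...] = tuple(DEFAULT_ARB_CLASSES)
    arb_extra_ingredients: tuple[str, ...] = tuple(ARB_EXTRA_INGREDIENTS)
    mra_subclasses: tuple[str, ...] = tuple(DEFAULT_MRA_SUBCLASSES)

    def __post_init__(self) -> None:
        for name in ("acei_classes", "acei_subclasses", "arb_classes", "mra_subclasses"):
            if any(not t for t in getattr(self, name)):
                raise ValueError(f"{name}: titles must be nonempty")


def default_vocabulary() -> DrugVocabulary:
    return DrugVocabulary()


def write_vocabulary(vocab: DrugVocabulary, directory) -> None:
    """Write the editable vocabulary files: one title per line for the
    .txt lists, single-column CSVs for the class/subclass tables."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / "gdmt_betablockers.txt").write_text(
        "\n".join(vocab.beta_blocker_ingredients) + "\n")
    (d / "acei_combinations.txt").write_text(
        "\n".join(vocab.acei_combinations) + "\n")
    pd.DataFrame({"class_title": vocab.acei_classes}).to_csv(
        d / "acei_classes.csv", index=False)
    pd.DataFrame({"subclass_title": vocab.acei_subclasses}).to_csv(
        d / "acei_subclasses.csv", index=False)
    pd.DataFrame({"class_title": vocab.arb_classes}).to_csv(
        d / "arb_classes.csv", index=False)
    pd.DataFrame({"subclass_title": vocab.mra_subclasses}).to_csv(
        d / "mra_subclasses.csv", index=False)


def load_vocabulary(directory) -> DrugVocabulary:
    d = Path(directory)

    def lines(name: str) -> tuple[str, ...]:
        return tuple(
            s for s in (d / name).read_text().splitlines() if s.strip()
        )

    return DrugVocabulary(
        beta_blocker_ingredients=lines("gdmt_betablockers.txt"),
        acei_combinations=lines("acei_combinations.txt"),
        acei_classes=tuple(pd.read_csv(d / "acei_classes.csv")["class_title"]),
        acei_subclasses=tuple(pd.read_csv(d / "acei_subclasses.csv")["subclass_title"]),
        arb_classes=tuple(pd.read_csv(d / "arb_classes.csv")["class_title"]),
        mra_subclasses=tuple(pd.read_csv(d / "mra_subclasses.csv")["subclass_title"]),
    )
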