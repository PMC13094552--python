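"""Tabular I/O and the core trait data model.

The analyses in this package consume two kinds of tables:

* a taxon x character matrix of ordinal morphological scores in [0, 3]
  (the suction-related characters, or a separate skull-shape block), and
* a taxon -> feeding-mode label table with two levels, ``Suction`` and
  ``Other``.

Scores are stored as floats: composite indices built from them (per-taxon
means) are fractional, and nothing in the scoring scheme forbids
intermediate scores. Characters carry a class tag — ``osteo_dental`` for
osteological/dentition traits, ``soft_tissue`` for traits unobservable in
fossils — and may be flagged *binary*, in which case only {0, 3} are legal
(the throat-grooves convention: the trait is either absent or strongly
present, never intermediate).
"""

from __future__ import annotations

import dataclasses
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

OSTEO_DENTAL = "osteo_dental"
SOFT_TISSUE = "soft_tissue"

SUCTION_LABEL = "Suction"
OTHER_LABEL = "Other"
FEEDING_LEVELS = (SUCTION_LABEL, OTHER_LABEL)

#: The ten suction-related characters, in canonical order. Two are soft
#: tissue (round mouth, throat grooves); throat grooves is scored 0-or-3.
SUCTION_CHARACTER_NAMES = (
    "blunt_wide_rostrum",
    "reduced_dentition",
    "dental_wear",
    "non_occluding_teeth_jaws",
    "robust_tongue_hyoid",
    "specialized_palate",
    "weak_jaw_adductors",
    "long_mandibular_symphysis",
    "round_mouth",
    "throat_grooves",
)
SOFT_TISSUE_NAMES = ("round_mouth", "throat_grooves")
BINARY_NAMES = ("throat_grooves",)


class DataValidationError(ValueError):
    """A trait table or label table violates the scoring contract."""


def normalize_name(name: str) -> str:
    """Canonical matching key for a taxon name.

    Spaces and underscores are interchangeable and matching is
    case-insensitive; trait tables and tree tip labels routinely disagree
    in exactly these ways.
    """
    return re.sub(r"[\s_]+", "_", name.strip()).casefold()


@dataclass(frozen=True)
class Character:
    """Descriptor for one morphological character column."""

    name: str
    char_class: str = OSTEO_DENTAL
    binary: bool = False

    def __post_init__(self) -> None:
        if self.char_class not in (OSTEO_DENTAL, SOFT_TISSUE):
            raise DataValidationError(
                f"character {self.name!r}: class must be one of "
                f"{OSTEO_DENTAL!r}, {SOFT_TISSUE!r}, got {self.char_class!r}"
            )


def suction_characters() -> list[Character]:
    """The canonical 10-character suction descriptor list."""
    return [
        Character(
            name=n,
            char_class=SOFT_TISSUE if n in SOFT_TISSUE_NAMES else OSTEO_DENTAL,
            binary=n in BINARY_NAMES,
        )
        for n in SUCTION_CHARACTER_NAMES
    ]


class CharacterMatrix:
    """Validated taxon x character grid of ordinal scores in [0, 3].

    Missing scores are ``NaN``. Binary characters admit only {0, 3}.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        characters: Sequence[Character],
        scores: np.ndarray,
    ) -> None:
        taxa = list(taxa)
        characters = list(characters)
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (len(taxa), len(characters)):
            raise DataValidationError(
                f"score grid shape {scores.shape} does not match "
                f"{len(taxa)} taxa x {len(characters)} characters"
            )
        if not characters:
            raise DataValidationError("at least one character is required")
        keys = [normalize_name(t) for t in taxa]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise DataValidationError(f"duplicate taxa: {dupes}")
        cnames = [c.name for c in characters]
        if len(set(cnames)) != len(cnames):
            raise DataValidationError("duplicate character names")
        self.taxa = taxa
        self.characters = characters
        self.scores = scores
        self._index = {k: i for i, k in enumerate(keys)}
        self._validate()

    def _validate(self) -> None:
        finite = np.isfinite(self.scores)
        bad = finite & ((self.scores < 0) | (self.scores > 3))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise DataValidationError(
                f"score {self.scores[i, j]} for taxon {self.taxa[i]!r}, "
                f"character {self.characters[j].name!r} is outside [0, 3]"
            )
        for j, ch in enumerate(self.characters):
            if not ch.binary:
                continue
            col = self.scores[:, j]
            illegal = np.isfinite(col) & (col != 0) & (col != 3)
            if illegal.any():
                i = int(np.flatnonzero(illegal)[0])
                raise DataValidationError(
                    f"character {ch.name!r} is binary (scored 0 = never "
                    f"present or 3 = strongly present) but taxon "
                    f"{self.taxa[i]!r} has score {col[i]}"
                )

    # -- access -----------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def character_names(self) -> list[str]:
        return [c.name for c in self.characters]

    def row(self, taxon: str) -> np.ndarray:
        return self.scores[self._index[normalize_name(taxon)]]

    def has_taxon(self, taxon: str) -> bool:
        return normalize_name(taxon) in self._index

    def column(self, character: str) -> np.ndarray:
        j = self.character_names.index(character)
        return self.scores[:, j]

    def osteo_dental_columns(self) -> np.ndarray:
        """Boolean mask over characters selecting the osteology/dentition set."""
        return np.array(
            [c.char_class == OSTEO_DENTAL for c in self.characters], dtype=bool
        )

    def subset_taxa(self, taxa: Iterable[str]) -> "CharacterMatrix":
        idx = [self._index[normalize_name(t)] for t in taxa]
        return CharacterMatrix(
            [self.taxa[i] for i in idx], self.characters, self.scores[idx]
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=pd.Index(self.taxa, name="taxon"),
            columns=self.character_names,
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, characters: Sequence[Character] | None = None
    ) -> "CharacterMatrix":
        if characters is None:
            characters = [Character(name=str(c)) for c in df.columns]
        else:
            by_name = {c.name: c for c in characters}
            missing = [c for c in df.columns if str(c) not in by_name]
            if missing:
                raise DataValidationError(
                    f"columns without a character descriptor: {missing}"
                )
            characters = [by_name[str(c)] for c in df.columns]
        numeric = df.apply(pd.to_numeric, errors="coerce")
        nonnum = df.notna() & numeric.isna()
        if nonnum.to_numpy().any():
            i, j = map(int, np.argwhere(nonnum.to_numpy())[0])
            raise DataValidationError(
                f"non-numeric score {df.iat[i, j]!r} for taxon "
                f"{df.index[i]!r}, character {df.columns[j]!r}"
            )
        return cls(
            [str(t) for t in df.index], characters, numeric.to_numpy(dtype=float)
        )


class LabelTable:
    """Mapping taxon -> feeding mode ('Suction' or 'Other')."""

    def __init__(self, mapping: Mapping[str, str]) -> None:
        self._labels: dict[str, str] = {}
        self._display: dict[str, str] = {}
        for taxon, label in mapping.items():
            key = normalize_name(taxon)
            if key in self._labels:
                raise DataValidationError(f"duplicate taxon {taxon!r} in labels")
            self._labels[key] = coerce_label(label)
            self._display[key] = taxon
        self.taxa = list(self._display.values())

    def __len__(self) -> int:
        return len(self._labels)

    def __contains__(self, taxon: str) -> bool:
        return normalize_name(taxon) in self._labels

    def __getitem__(self, taxon: str) -> str:
        return self._labels[normalize_name(taxon)]

    def items(self):
        return ((self._display[k], v) for k, v in self._labels.items())

    def labels_for(self, taxa: Sequence[str]) -> np.ndarray:
        return np.array([self[t] for t in taxa], dtype=object)

    def counts(self) -> dict[str, int]:
        out = {lvl: 0 for lvl in FEEDING_LEVELS}
        for v in self._labels.values():
            out[v] += 1
        return out


def coerce_label(label: str) -> str:
    """Normalize a feeding-mode string to 'Suction' or 'Other'."""
    s = str(label).strip().casefold()
    for lvl in FEEDING_LEVELS:
        if s == lvl.casefold():
            return lvl
    raise DataValidationError(
        f"unknown feeding-mode label {label!r}; allowed levels are "
        f"{list(FEEDING_LEVELS)}"
    )


@dataclass
class AnalysisConfig:
    """Run-level knobs shared across pipeline stages."""

    seed: int = 0
    test_fraction: float = 0.25
    n_permutations: int = 1000
    n_bm_simulations: int = 1000
    positive_class: str = SUCTION_LABEL
    missing_policy: str = "renormalize"  # or "error"

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_permutations < 1 or self.n_bm_simulations < 1:
            raise ValueError("permutation/simulation counts must be positive")
        if self.missing_policy not in ("error", "renormalize"):
            raise ValueError("missing_policy must be 'error' or 'renormalize'")


# -- file readers ---------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, index_col=0, encoding="utf-8")


def read_character_matrix(
    path: str | Path, characters: Sequence[Character] | None = None
) -> CharacterMatrix:
    """Read a CSV/TSV score matrix (column 1 = taxon, header = characters).

    ``characters`` supplies class/binary tags; omitted, every column is
    treated as a continuous osteology/dentition character.
    """
    return CharacterMatrix.from_dataframe(_read_table(path), characters)


def read_suction_matrix(path: str | Path) -> CharacterMatrix:
    """Read the 10-character suction matrix with its canonical schema."""
    return read_character_matrix(path, suction_characters())


def read_label_table(path: str | Path) -> LabelTable:
    """Read a two-column taxon,label CSV/TSV into a LabelTable."""
    df = _read_table(path)
    if df.shape[1] != 1:
        raise DataValidationError(
            f"label table must have exactly two columns (taxon, label); "
            f"got {df.shape[1] + 1}"
        )
    return LabelTable({str(t): str(v) for t, v in df.iloc[:, 0].items()})


def write_character_matrix(matrix: CharacterMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    matrix.to_dataframe().to_csv(path, sep=sep, encoding="utf-8")


def write_label_table(labels: LabelTable, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    pd.DataFrame(
        [(t, v) for t, v in labels.items()], columns=["taxon", "feeding_mode"]
    ).to_csv(path, sep=sep, index=False, encoding="utf-8")


# -- JSON reports ---------------------------------------------------------

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _jsonable(float(obj))
    if isinstance(obj, float):
        return None if math.isnan(obj) else obj
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return {
            "__dataframe__": True,
            "index_name": obj.index.name,
            "columns": [str(c) for c in obj.columns],
            "records": _jsonable(obj.reset_index().to_dict(orient="records")),
        }
    return obj


def write_report(result, path: str | Path, stage: str = "",
                 config: AnalysisConfig | None = None) -> None:
    """Serialize a stage output to a JSON report.

    Floats are emitted with repr round-tripping (17 significant digits),
    so rereading reproduces values to well beyond 12 significant digits.
    """
    payload = {"stage": stage, "result": _jsonable(result)}
    if config is not None:
        payload["config"] = _jsonable(config)
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
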