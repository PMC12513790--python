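"""Variant datasets and predictor score tracks.

Variant tables are pandas DataFrames with columns ``human_pos`` (1-based),
``ref_aa``/``alt_aa`` (1-letter codes), ``label`` (one of MH, CCD, RRD,
recessive, benign) and ``source``. Score tables are tidy DataFrames with
columns ``variant`` (canonical ``p.<ref><pos><alt>`` key), ``predictor``,
``score`` and ``orientation``; missing scores are simply absent rows, never
zero-filled.
"""

from __future__ import annotations

import re
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

PHENOTYPES = ("MH", "CCD", "RRD", "recessive")
DOMINANT = ("MH", "CCD", "RRD")
LABELS = PHENOTYPES + ("benign",)

VARIANT_COLUMNS = ["human_pos", "ref_aa", "alt_aa", "label", "source"]

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

_KEY_RE = re.compile(r"^(?:p\.)?([A-Za-z]{1,3})(\d+)([A-Za-z]{1,3})$")


def variant_key(ref_aa: str, human_pos: int, alt_aa: str) -> str:
    """Canonical variant key, e.g. ``p.R614C``."""
    return f"p.{ref_aa}{int(human_pos)}{alt_aa}"


def parse_variant_key(key: str) -> tuple[str, int, str]:
    """Parse a variant key; 3-letter amino-acid codes are also accepted
    (``p.Arg614Cys`` → ``('R', 614, 'C')``)."""
    m = _KEY_RE.match(key.strip())
    if not m:
        raise ValueError(f"cannot parse variant key {key!r}")
    ref, pos, alt = m.groups()

    def to1(code: str) -> str:
        if len(code) == 1:
            return code.upper()
        aa = _AA3TO1.get(code.upper())
        if aa is None:
            raise ValueError(f"unknown amino-acid code {code!r} in {key!r}")
        return aa

    return to1(ref), int(pos), to1(alt)


def validate_variant_table(df: pd.DataFrame, human_seq: str | None = None) -> pd.DataFrame:
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns and c != "source"]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    df = df.copy()
    if "source" not in df.columns:
        df["source"] = ""
    bad = sorted(set(df["label"]) - set(LABELS))
    if bad:
        raise ValueError(f"unknown labels {bad}; allowed: {list(LABELS)}")
    if human_seq is not None:
        pos = df["human_pos"].astype(int)
        out = df[(pos < 1) | (pos > len(human_seq))]
        if not out.empty:
            raise ValueError(f"variant positions outside sequence: {sorted(out['human_pos'])}")
        seq_ref = pos.map(lambda p: human_seq[p - 1])
        wrong = df[df["ref_aa"] != seq_ref]
        if not wrong.empty:
            keys = [variant_key(r.ref_aa, r.human_pos, r.alt_aa) for r in wrong.itertuples()]
            raise ValueError(f"reference residues disagree with sequence: {keys}")
    return df


def assemble_datasets(disease: pd.DataFrame, population: pd.DataFrame,
                      human_seq: str | None = None) -> pd.DataFrame:
    """Merge a disease-variant table with a population table into one
    labelled dataset.

    Population variants also present in the disease set are dropped from the
    benign side (the two classes stay mutually exclusive); duplicates are
    collapsed. Conflicting phenotype labels for one variant within the
    disease table raise a ``ValueError`` listing the conflicts.
    """
    disease = validate_variant_table(disease, human_seq)
    population = validate_variant_table(population, human_seq)

    ident = ["human_pos", "ref_aa", "alt_aa"]
    n_labels = disease.groupby(ident)["label"].nunique()
    conflicts = n_labels[n_labels > 1]
    if not conflicts.empty:
        keys = [variant_key(r, p, a) for (p, r, a) in conflicts.index]
        raise ValueError(f"conflicting phenotype labels for: {keys}")
    disease = disease.drop_duplicates(subset=ident)

    population = population.copy()
    population["label"] = "benign"
    population = population.drop_duplicates(subset=ident)
    in_disease = pd.MultiIndex.from_frame(population[ident]).isin(
        pd.MultiIndex.from_frame(disease[ident])
    )
    population = population[~in_disease]

    out = pd.concat([disease, population], ignore_index=True)
    out["variant"] = [
        variant_key(r.ref_aa, r.human_pos, r.alt_aa) for r in out.itertuples()
    ]
    return out[["variant"] + VARIANT_COLUMNS]


def segment_sequence(length: int, segment_length: int = 800, overlap: int = 50) -> list[tuple[int, int]]:
    """Split a sequence of ``length`` residues into overlapping segments.

    Segment k starts at ``1 + k*(segment_length − overlap)``; the final
    segment is truncated at ``length``. Long proteins are scored by
    predictors in such windows and merged back with
    :func:`merge_segment_scores`.
    """
    if length < 1:
        raise ValueError("length must be ≥ 1")
    if not (0 <= overlap < segment_length):
        raise ValueError(f"need 0 ≤ overlap < segment_length, got {overlap} / {segment_length}")
    segments = []
    start = 1
    step = segment_length - overlap
    while True:
        end = min(start + segment_length - 1, length)
        segments.append((start, end))
        if end >= length:
            break
        start += step
    return segments


def merge_segment_scores(segments: Sequence[tuple[tuple[int, int], np.ndarray]],
                         length: int | None = None) -> np.ndarray:
    """Merge per-segment per-position score vectors into one track.

    Positions covered by several segments receive the arithmetic mean of
    their (non-missing) scores; all-missing positions stay NaN.
    """
    if not segments:
        raise ValueError("no segments given")
    for (start, end), vec in segments:
        if end - start + 1 != len(vec):
            raise ValueError(f"segment ({start},{end}) expects {end - start + 1} scores, got {len(vec)}")
    if length is None:
        length = max(end for (_, end), _ in segments)
    total = np.zeros(length)
    count = np.zeros(length)
    for (start, end), vec in segments:
        vec = np.asarray(vec, dtype=float)
        ok = np.isfinite(vec)
        sl = slice(start - 1, end)
        total[sl] += np.where(ok, vec, 0.0)
        count[sl] += ok
    with np.errstate(invalid="ignore"):
        merged = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return merged


def rank_normalise(values) -> np.ndarray:
    """Rank-normalise a vector to (0, 1]: ascending midranks divided by the
    number of finite values. Missing (NaN) values stay missing."""
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    n = int(finite.sum())
    if n == 0:
        raise ValueError("rank_normalise requires at least one finite value")
    out = np.full(arr.shape, np.nan)
    out[finite] = rankdata(arr[finite], method="average") / n
    return out


def read_variants_tsv(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a variant TSV/CSV; ``column_map`` renames file headers onto the
    canonical columns."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=column_map)
    return validate_variant_table(df)


def read_scores_tsv(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=column_map)
    required = {"variant", "predictor", "score", "orientation"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    df = df.dropna(subset=["score"]).drop_duplicates(subset=["variant", "predictor"])
    per_pred = df.groupby("predictor")["orientation"].nunique()
    bad = per_pred[per_pred > 1]
    if not bad.empty:
        raise ValueError(f"inconsistent orientation for predictors: {list(bad.index)}")
    return df
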