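"""File I/O: Oxford GEN probability files, hard-call TSVs, results, config.

Genotype coding throughout: 0/1/2 = copies of allele B (the coded/risk
allele), matching the GEN convention that the three probabilities per
individual are ordered (AA, AB, BB).  GEN files are text-rounded, so triples
are accepted when they sum to 1 within 0.05 and renormalized on load.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .core import PosteriorMatrix, TestResult
from .simulate import ImputationConfig, PenetranceModel
from .study import StudyConfig, StudyResult

__all__ = [
    "GenRecord",
    "read_gen",
    "read_gen_pair",
    "write_gen",
    "read_calls_tsv",
    "write_calls_tsv",
    "results_to_frame",
    "write_results_tsv",
    "write_study_tsv",
    "load_study_config",
]

_TRIPLE_TOL = 0.05


@dataclass(frozen=True)
class GenRecord:
    """One SNP row of an Oxford GEN file."""

    snp_id: str
    rs_id: str
    position: int  # 1-based, display only
    alleleA: str
    alleleB: str
    probs: np.ndarray  # n x 3, ordered (AA, AB, BB)

    @property
    def n(self) -> int:
        return self.probs.shape[0]


def _parse_gen_line(line: str, lineno: int, path: str) -> GenRecord:
    fields = line.split()
    if len(fields) < 8 or (len(fields) - 5) % 3 != 0:
        raise ValueError(
            f"{path}:{lineno}: expected 5 + 3n fields, got {len(fields)}"
        )
    try:
        vals = np.array([float(x) for x in fields[5:]])
    except ValueError as err:
        raise ValueError(f"{path}:{lineno}: non-numeric probability: {err}") from err
    probs = vals.reshape(-1, 3)
    sums = probs.sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > _TRIPLE_TOL)
    if bad.size:
        raise ValueError(
            f"{path}:{lineno}: probability triple for individual {bad[0]} "
            f"sums to {sums[bad[0]]:.4f} (outside 1 +/- {_TRIPLE_TOL})"
        )
    probs = probs / sums[:, None]
    return GenRecord(
        snp_id=fields[0],
        rs_id=fields[1],
        position=int(fields[2]),
        alleleA=fields[3],
        alleleB=fields[4],
        probs=probs,
    )


def read_gen(path: Union[str, Path], rsid: Optional[str] = None) -> GenRecord:
    """Read one SNP record from a GEN file; multi-SNP files need ``rsid``."""
    path = str(path)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            records.append(_parse_gen_line(line, lineno, path))
    if not records:
        raise ValueError(f"{path}: no SNP rows")
    if rsid is not None:
        match = [r for r in records if rsid in (r.rs_id, r.snp_id)]
        if not match:
            raise ValueError(f"{path}: no SNP with id {rsid!r}")
        return match[0]
    if len(records) > 1:
        raise ValueError(
            f"{path}: {len(records)} SNP rows; select one with an rsid"
        )
    return records[0]


def _count_sample_file(path: Union[str, Path]) -> int:
    # .sample files have two header lines (names and types)
    with open(path) as fh:
        rows = [ln for ln in fh if ln.strip()]
    if len(rows) < 2:
        raise ValueError(f"{path}: malformed sample file")
    return len(rows) - 2


def read_gen_pair(
    path_G: Union[str, Path],
    path_H: Union[str, Path],
    sample_path: Optional[Union[str, Path]] = None,
    rsid_G: Optional[str] = None,
    rsid_H: Optional[str] = None,
) -> PosteriorMatrix:
    """Load the posterior matrix for a SNP pair from two GEN files."""
    rec_G = read_gen(path_G, rsid=rsid_G)
    rec_H = read_gen(path_H, rsid=rsid_H)
    if rec_G.n != rec_H.n:
        raise ValueError(
            f"sample count mismatch: {path_G} has {rec_G.n}, {path_H} has {rec_H.n}"
        )
    if sample_path is not None:
        n_samples = _count_sample_file(sample_path)
        if n_samples != rec_G.n:
            raise ValueError(
                f"sample file lists {n_samples} individuals but GEN files "
                f"carry {rec_G.n}"
            )
    return PosteriorMatrix(pG=rec_G.probs, pH=rec_H.probs)


def write_gen(path: Union[str, Path], record: GenRecord, decimals: int = 6) -> None:
    """Write one SNP record as a GEN row."""
    with open(path, "w") as fh:
        head = f"{record.snp_id} {record.rs_id} {record.position} {record.alleleA} {record.alleleB}"
        body = " ".join(
            f"{x:.{decimals}f}" for x in np.asarray(record.probs).ravel()
        )
        fh.write(head + " " + body + "\n")


def read_calls_tsv(path: Union[str, Path]) -> tuple[np.ndarray, np.ndarray]:
    """Read hard calls from a TSV with columns sample, G, H (values 0/1/2)."""
    path = str(path)
    g, h, seen = [], [], set()
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: no samples")
        cols = [c.strip() for c in header]
        if cols[:3] != ["sample", "G", "H"]:
            raise ValueError(f"{path}: expected columns sample, G, H; got {cols}")
        for lineno, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            sid = row[0]
            if sid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate sample id {sid!r}")
            seen.add(sid)
            for col, bucket in ((1, g), (2, h)):
                try:
                    val = int(row[col])
                except (ValueError, IndexError) as err:
                    raise ValueError(f"{path}:{lineno}: bad genotype: {err}") from err
                if val not in (0, 1, 2):
                    raise ValueError(
                        f"{path}:{lineno}: genotype {val} not in {{0,1,2}}"
                    )
                bucket.append(val)
    if not g:
        raise ValueError(f"{path}: no samples")
    return np.array(g), np.array(h)


def write_calls_tsv(
    path: Union[str, Path], G: Sequence[int], H: Sequence[int]
) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tG\tH\n")
        for i, (a, b) in enumerate(zip(G, H)):
            fh.write(f"s{i}\t{int(a)}\t{int(b)}\n")


def results_to_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        if isinstance(r.df_or_weights, str):
            ref, weights = r.df_or_weights, ""
        else:
            ref = f"chibar[{r.df_or_weights.cone}]"
            weights = ",".join(f"{w:.5f}" for w in r.df_or_weights.w)
        rows.append(
            {
                "method": r.method,
                "statistic": r.statistic,
                "pvalue": r.pvalue,
                "variance": r.variance_provenance,
                "reference": ref,
                "weights": weights,
            }
        )
    return pd.DataFrame(rows)


def write_results_tsv(path: Union[str, Path], results: Sequence[TestResult]) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)


def write_study_tsv(
    path: Union[str, Path],
    result: StudyResult,
    pvalue_path: Optional[Union[str, Path]] = None,
) -> None:
    pd.DataFrame(result.summary_rows()).to_csv(path, sep="\t", index=False)
    if pvalue_path is not None:
        pd.DataFrame(result.pvalues).to_csv(pvalue_path, sep="\t", index=False)


_STUDY_KEYS = {
    "model", "maf_G", "maf_H", "imp_G", "imp_H", "n_cases", "replicates",
    "alpha", "methods", "seed", "chibar_draws", "zero_policy", "grouping",
}
_MODEL_KEYS = {"kind", "f", "g", "mu", "alpha", "gamma"}
_IMP_KEYS = {"p", "q", "r", "reference_haplotypes"}


def _check_keys(given: dict, allowed: set, context: str) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(f"unknown {context} keys: {sorted(unknown)}")


def load_study_config(path: Union[str, Path]) -> StudyConfig:
    """Build a StudyConfig from a YAML file (unknown keys are rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    _check_keys(raw, _STUDY_KEYS, "study config")
    if "model" not in raw:
        raise ValueError(f"{path}: missing required key 'model'")
    model_raw = dict(raw.pop("model"))
    _check_keys(model_raw, _MODEL_KEYS, "model")
    for key in ("alpha", "gamma"):
        if key in model_raw:
            model_raw[key] = tuple(model_raw[key])
    model = PenetranceModel(**model_raw)
    kwargs: dict = {"model": model}
    for imp_key in ("imp_G", "imp_H"):
        if imp_key in raw:
            imp_raw = dict(raw.pop(imp_key))
            _check_keys(imp_raw, _IMP_KEYS, imp_key)
            kwargs[imp_key] = ImputationConfig(**imp_raw)
    if "methods" in raw:
        raw["methods"] = tuple(raw["methods"])
    kwargs.update(raw)
    return StudyConfig(**kwargs)
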