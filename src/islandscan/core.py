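"""Shared in-memory containers for the divergence-scan pipeline.

Genotypes are held as a samples x sites matrix of alternate-allele dosages
(0..ploidy of the sample, or -1 for missing). Sites live in a pandas
DataFrame sorted by (contig, pos) with the per-site depth and mapping-quality
fields the SNP filters act on. All internal coordinates are 0-based
half-open; VCF I/O converts to and from 1-based positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

SITE_COLUMNS = ["contig", "pos", "ref", "alt", "depth", "mq"]


class ConfigurationError(ValueError):
    """A configuration field is invalid; the message names the field."""


@dataclass
class GenotypeMatrix:
    """Alternate-allele dosages for a cohort of possibly mixed ploidy.

    Parameters
    ----------
    dosages
        Integer array of shape (n_samples, n_sites); entries in
        ``[0, ploidy[s]]`` or :data:`MISSING`.
    sample_ids
        Ordered sample names, one per row.
    ploidy
        Per-sample ploidy (2, 4, 6, ...), one per row.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    ploidy: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        self.ploidy = np.asarray(self.ploidy, dtype=np.int64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x sites)")
        if len(self.sample_ids) != self.dosages.shape[0]:
            raise ValueError("sample_ids length does not match dosage rows")
        if self.ploidy.shape != (self.dosages.shape[0],):
            raise ValueError("ploidy must have one entry per sample")
        bad = (self.dosages != MISSING) & (
            (self.dosages < 0) | (self.dosages > self.ploidy[:, None])
        )
        if bad.any():
            raise ValueError("dosage exceeds sample ploidy or is negative")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def sample_indices(self, sample_ids) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.asarray([index[s] for s in sample_ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - message matters, not path
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[:, mask_or_index], list(self.sample_ids), self.ploidy.copy()
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages.copy(), list(self.sample_ids), self.ploidy.copy()
        )


def make_site_table(contig, pos, ref, alt, depth, mq) -> pd.DataFrame:
    """Assemble a site table and enforce its invariants (sorted, unique, biallelic)."""
    df = pd.DataFrame(
        {
            "contig": pd.Series(contig, dtype="string"),
            "pos": pd.Series(pos, dtype="int64"),
            "ref": pd.Series(ref, dtype="string"),
            "alt": pd.Series(alt, dtype="string"),
            "depth": pd.Series(depth, dtype="float64"),
            "mq": pd.Series(mq, dtype="float64"),
        }
    )
    validate_site_table(df)
    return df


def validate_site_table(sites: pd.DataFrame) -> None:
    missing = [c for c in SITE_COLUMNS if c not in sites.columns]
    if missing:
        raise ValueError(f"site table missing columns: {missing}")
    by_contig = sites.groupby("contig", sort=False, observed=True)["pos"]
    if not by_contig.apply(lambda p: p.is_monotonic_increasing and p.is_unique).all():
        raise ValueError("site table positions must be sorted and unique per contig")


@dataclass
class PopulationMap:
    """Mapping sample_id -> population label."""

    assignments: dict = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path) -> "PopulationMap":
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["sample_id", "population"], dtype=str)
        return cls(dict(zip(df["sample_id"], df["population"])))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for s, p in self.assignments.items():
                fh.write(f"{s}\t{p}\n")

    @property
    def populations(self) -> list:
        seen: dict = {}
        for p in self.assignments.values():
            seen.setdefault(p, None)
        return list(seen)

    def samples(self, population: str) -> list:
        out = [s for s, p in self.assignments.items() if p == population]
        if not out:
            raise KeyError(f"unknown population label {population!r}")
        return out

    def check_covers(self, sample_ids) -> None:
        unlabeled = [s for s in sample_ids if s not in self.assignments]
        if unlabeled:
            raise ValueError(f"samples without population label: {unlabeled[:5]}")
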