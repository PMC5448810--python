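"""In-memory model, validation and JSON I/O for complete binary genotype-fitness maps.

A map assigns measured fitness to every combination of ``L`` biallelic sites:
all ``2**L`` genotypes, written as binary strings over ``{0, 1}`` where ``0`` is
the ancestral (wildtype) allele and ``1`` the derived (mutant) allele.  The
canonical genotype order used by every array in this package is binary-integer
order with site 0 as the *leftmost* character, so ``"000"`` (the ancestral
genotype) has index 0 and ``"111"`` (the fully derived genotype) has index
``2**L - 1``.

The JSON schema is::

    {
      "n_sites": 2,
      "wildtype": "00",                    # optional cross-check
      "genotypes": {
        "00": {"replicates": [1.0, 1.02]}, # or {"mean": 1.01, "std": 0.01}
        ...
      }
    }

The reader is tolerant: each genotype may carry either a replicate list or a
``mean``/``std`` pair; when both are present the replicates win.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "MapValidationError",
    "GenotypeEncodingError",
    "GenotypeFitnessMap",
    "HypercubeEdge",
    "genotype_index",
    "index_to_genotype",
    "genotype_matrix",
    "forward_edges",
    "read_map_json",
    "read_maps_json",
    "write_map_json",
]


class MapValidationError(ValueError):
    """A genotype-fitness map violates the complete-hypercube contract."""


class GenotypeEncodingError(ValueError):
    """A genotype label is not a binary string of the expected length."""


def genotype_index(label: str, n_sites: int | None = None) -> int:
    """Canonical index of a genotype label.

    The label is read as a binary number with site 0 as the most significant
    (leftmost) digit, so ``"01000"`` (mutant at site 1 only) has index 8.
    """
    if not isinstance(label, str) or len(label) == 0:
        raise GenotypeEncodingError(f"genotype label must be a non-empty string, got {label!r}")
    if n_sites is not None and len(label) != n_sites:
        raise GenotypeEncodingError(
            f"genotype {label!r} has {len(label)} sites, expected {n_sites}"
        )
    if set(label) - {"0", "1"}:
        raise GenotypeEncodingError(f"genotype {label!r} contains characters outside {{0,1}}")
    return int(label, 2)


def index_to_genotype(index: int, n_sites: int) -> str:
    """Inverse of :func:`genotype_index`."""
    if not 0 <= index < 2**n_sites:
        raise GenotypeEncodingError(f"index {index} out of range for {n_sites} sites")
    return format(index, f"0{n_sites}b")


def genotype_matrix(n_sites: int) -> np.ndarray:
    """The ``2**L x L`` matrix of 0/1 mutation indicators in canonical order.

    Entry ``(i, j)`` is 1 when genotype ``i`` carries the derived allele at
    site ``j``.
    """
    idx = np.arange(2**n_sites)
    shifts = n_sites - 1 - np.arange(n_sites)
    return ((idx[:, None] >> shifts[None, :]) & 1).astype(float)


@dataclass(frozen=True)
class HypercubeEdge:
    """A single forward mutational step (gain of one derived allele)."""

    from_genotype: str
    to_genotype: str
    site: int

    @property
    def from_index(self) -> int:
        return genotype_index(self.from_genotype)

    @property
    def to_index(self) -> int:
        return genotype_index(self.to_genotype)


@dataclass
class GenotypeFitnessMap:
    """A complete binary genotype-fitness map.

    Parameters
    ----------
    n_sites:
        Number of biallelic sites ``L``.
    fitness_mean:
        Per-genotype mean fitness in canonical order (length ``2**L``).
    fitness_std:
        Per-genotype standard deviation of the fitness measurements.
    fitness_replicates:
        Optional list of per-genotype replicate arrays.  When present,
        ``fitness_mean``/``fitness_std`` are recomputed from the replicates
        (sample std with ``ddof=1``; a single replicate is recorded as std 0).
    name:
        Free-text dataset label carried through the pipeline.
    """

    n_sites: int
    fitness_mean: np.ndarray
    fitness_std: np.ndarray | None = None
    fitness_replicates: list[np.ndarray] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise MapValidationError(f"n_sites must be >= 1, got {self.n_sites}")
        n = 2**self.n_sites
        self.fitness_mean = np.asarray(self.fitness_mean, dtype=float)
        if self.fitness_mean.shape != (n,):
            raise MapValidationError(
                f"expected {n} fitness values for L={self.n_sites}, "
                f"got shape {self.fitness_mean.shape}"
            )
        if self.fitness_replicates is not None:
            if len(self.fitness_replicates) != n:
                raise MapValidationError(
                    f"expected {n} replicate lists, got {len(self.fitness_replicates)}"
                )
            reps = [np.asarray(r, dtype=float).ravel() for r in self.fitness_replicates]
            for i, r in enumerate(reps):
                if r.size == 0:
                    raise MapValidationError(
                        f"genotype {index_to_genotype(i, self.n_sites)!r} has no replicates"
                    )
                if not np.all(np.isfinite(r)):
                    raise MapValidationError(
                        f"genotype {index_to_genotype(i, self.n_sites)!r} has non-finite fitness"
                    )
            self.fitness_replicates = reps
            self.fitness_mean = np.array([r.mean() for r in reps])
            self.fitness_std = np.array(
                [r.std(ddof=1) if r.size > 1 else 0.0 for r in reps]
            )
        if self.fitness_std is None:
            self.fitness_std = np.zeros(n)
        self.fitness_std = np.asarray(self.fitness_std, dtype=float)
        if self.fitness_std.shape != (n,):
            raise MapValidationError(
                f"expected {n} std values, got shape {self.fitness_std.shape}"
            )
        if not np.all(np.isfinite(self.fitness_mean)):
            bad = int(np.flatnonzero(~np.isfinite(self.fitness_mean))[0])
            raise MapValidationError(
                f"genotype {index_to_genotype(bad, self.n_sites)!r} has non-finite mean fitness"
            )
        if np.any(self.fitness_std < 0):
            bad = int(np.flatnonzero(self.fitness_std < 0)[0])
            raise MapValidationError(
                f"genotype {index_to_genotype(bad, self.n_sites)!r} has negative fitness std"
            )

    # -- structural accessors ------------------------------------------------

    @property
    def n_genotypes(self) -> int:
        return 2**self.n_sites

    @property
    def genotype_labels(self) -> list[str]:
        return [index_to_genotype(i, self.n_sites) for i in range(self.n_genotypes)]

    @property
    def ancestral_index(self) -> int:
        """Index of the all-ancestral (all-0) genotype: always 0."""
        return 0

    @property
    def derived_index(self) -> int:
        """Index of the fully derived (all-1) genotype: always ``2**L - 1``."""
        return self.n_genotypes - 1

    @property
    def genotype_matrix(self) -> np.ndarray:
        return genotype_matrix(self.n_sites)

    def with_means(
        self,
        fitness_mean: np.ndarray,
        fitness_std: np.ndarray | None = None,
        name: str | None = None,
    ) -> "GenotypeFitnessMap":
        """A copy of this map with replaced means (replicates are dropped).

        Stds default to this map's stds, matching the convention that derived
        maps (truncations, pseudoreplicates) inherit the measurement
        uncertainty of their source.
        """
        return GenotypeFitnessMap(
            n_sites=self.n_sites,
            fitness_mean=np.asarray(fitness_mean, dtype=float).copy(),
            fitness_std=(self.fitness_std if fitness_std is None else fitness_std).copy(),
            name=self.name if name is None else name,
        )


def forward_edges(gmap: GenotypeFitnessMap | int) -> list[HypercubeEdge]:
    """All single-mutation forward edges (0 -> 1 at exactly one site).

    Accepts a map or a site count; returns ``L * 2**(L-1)`` edges.
    """
    L = gmap if isinstance(gmap, int) else gmap.n_sites
    edges = []
    for i in range(2**L):
        label = index_to_genotype(i, L)
        for j in range(L):
            if label[j] == "0":
                to_label = label[:j] + "1" + label[j + 1 :]
                edges.append(HypercubeEdge(label, to_label, j))
    return edges


# -- JSON I/O ----------------------------------------------------------------


def _parse_genotype_entry(label: str, entry) -> tuple[np.ndarray | None, float, float]:
    """Return (replicates, mean, std) for one genotype entry; replicates win."""
    if isinstance(entry, (list, tuple)):
        entry = {"replicates": entry}
    if not isinstance(entry, dict):
        raise MapValidationError(f"genotype {label!r}: entry must be an object or list")
    if "replicates" in entry:
        reps = np.asarray(entry["replicates"], dtype=float).ravel()
        if reps.size == 0:
            raise MapValidationError(f"genotype {label!r}: empty replicate list")
        if not np.all(np.isfinite(reps)):
            raise MapValidationError(f"genotype {label!r}: non-numeric fitness value")
        std = reps.std(ddof=1) if reps.size > 1 else 0.0
        return reps, float(reps.mean()), float(std)
    if "mean" in entry:
        mean = float(entry["mean"])
        std = float(entry.get("std", 0.0))
        if not np.isfinite(mean) or not np.isfinite(std):
            raise MapValidationError(f"genotype {label!r}: non-numeric fitness value")
        return None, mean, std
    raise MapValidationError(f"genotype {label!r}: needs 'replicates' or 'mean'")


def _map_from_dict(doc: dict, name: str = "") -> GenotypeFitnessMap:
    if "genotypes" not in doc:
        raise MapValidationError("document has no 'genotypes' object")
    genotypes = doc["genotypes"]
    labels = list(genotypes)
    if not labels:
        raise MapValidationError("empty genotype table")
    lengths = {len(lab) for lab in labels}
    if len(lengths) != 1:
        raise MapValidationError(f"ragged genotype labels: site counts {sorted(lengths)}")
    L = int(doc.get("n_sites", lengths.pop()))
    if len(labels[0]) != L:
        raise MapValidationError(
            f"n_sites={L} but genotype labels have {len(labels[0])} sites"
        )
    wildtype = doc.get("wildtype")
    if wildtype is not None and wildtype != "0" * L:
        raise MapValidationError(
            f"wildtype {wildtype!r} is not the all-ancestral genotype {'0' * L!r}"
        )

    n = 2**L
    seen: set[int] = set()
    reps: list = [None] * n
    mean = np.empty(n)
    std = np.empty(n)
    for label, entry in genotypes.items():
        idx = genotype_index(label, L)
        if idx in seen:
            raise MapValidationError(f"duplicate genotype {label!r}")
        seen.add(idx)
        reps[idx], mean[idx], std[idx] = _parse_genotype_entry(label, entry)
    if len(seen) != n:
        missing = index_to_genotype(min(set(range(n)) - seen), L)
        raise MapValidationError(
            f"incomplete hypercube: missing genotype {missing!r} "
            f"({n - len(seen)} of {n} genotypes absent)"
        )
    gmap = GenotypeFitnessMap(n_sites=L, fitness_mean=mean, fitness_std=std, name=name)
    if any(r is not None for r in reps):
        # keep replicates only when every genotype has them; a mixed file keeps
        # the summary statistics (replicate lists would be ragged with Nones)
        if all(r is not None for r in reps):
            gmap = GenotypeFitnessMap(
                n_sites=L, fitness_mean=mean, fitness_replicates=reps, name=name
            )
    return gmap


def read_map_json(path) -> GenotypeFitnessMap:
    """Read a single genotype-fitness map from a JSON file."""
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    if "genotypes" not in doc and "datasets" in doc:
        raise MapValidationError(
            "file holds multiple datasets; use read_maps_json()"
        )
    return _map_from_dict(doc, name=doc.get("name", path.stem))


def read_maps_json(path) -> dict[str, GenotypeFitnessMap]:
    """Read a collection ``{"datasets": {name: <map object>}}`` of maps."""
    with open(path) as fh:
        doc = json.load(fh)
    if "datasets" not in doc:
        return {Path(path).stem: _map_from_dict(doc, name=Path(path).stem)}
    return {
        name: _map_from_dict(sub, name=name) for name, sub in doc["datasets"].items()
    }


def write_map_json(gmap: GenotypeFitnessMap, path) -> None:
    """Write a map in the package's JSON schema (replicates when present)."""
    genotypes = {}
    for i, label in enumerate(gmap.genotype_labels):
        if gmap.fitness_replicates is not None:
            genotypes[label] = {"replicates": list(map(float, gmap.fitness_replicates[i]))}
        else:
            genotypes[label] = {
                "mean": float(gmap.fitness_mean[i]),
                "std": float(gmap.fitness_std[i]),
            }
    doc = {
        "n_sites": gmap.n_sites,
        "wildtype": "0" * gmap.n_sites,
        "name": gmap.name,
        "genotypes": genotypes,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")
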