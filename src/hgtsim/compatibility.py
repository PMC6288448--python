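"""Generators for the four mechanism compatibility matrices.

Each horizontal transfer mechanism modulates its maximal rate constant with an
N-by-N matrix ``alpha`` of pairwise donor->recipient compatibilities in
[0, 1]: rows index donor species, columns index recipient species.  The four
rulesets are:

* **conjugation** — a randomly chosen "super-permissive core" of ~15% of
  species receives at uniform[0, 1] efficiency; every other recipient column
  is attenuated 25-fold (uniform[0, 1/25]).
* **transformation** — ~1% of species are naturally transformable; their
  recipient columns are 1, all other entries 0.
* **transduction** — derived from a modular, within-module-nested phage-host
  network: compatibility is the fraction of the donor's phages that also
  infect the recipient, and 0 across modules.
* **vesicle-mediated transfer** — every species gets independent uniform[0,1]
  donor and recipient efficiencies; each pair's compatibility is the product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "CompatibilityMatrix",
    "PhageHostNetwork",
    "ValidationReport",
    "conjugation_alpha",
    "transformation_alpha",
    "build_phage_host_network",
    "transduction_alpha",
    "vesicle_alpha",
    "validate_alpha",
    "module_sizes_linear",
    "default_species_ids",
]

DEFAULT_SPC_FRACTION = 0.15
DEFAULT_SPC_ATTENUATION = 25.0
DEFAULT_P_TRANSFORMABLE = 0.01

RngLike = "int | None | np.random.Generator"


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def default_species_ids(n: int) -> list[str]:
    return [f"sp{i + 1}" for i in range(n)]


@dataclass(frozen=True)
class PhageHostNetwork:
    """Modular, within-module-nested phage-host infection structure.

    Species are partitioned into modules; a module of size ``s`` has ``s``
    module-local phages.  Hosts in a module are ranked by permissiveness
    (a uniform random permutation of 1..s) and the host of rank ``r`` is
    infected by phages 1..r, so phage 1 is the module generalist and any two
    hosts' phage sets are nested.

    ``module_of[i]`` is the module index of species ``i`` and
    ``phage_count[i]`` its permissiveness rank (phage-set size).
    """

    module_of: np.ndarray
    phage_count: np.ndarray
    n_modules: int

    def __post_init__(self) -> None:
        if self.module_of.shape != self.phage_count.shape:
            raise InvalidInputError("module_of and phage_count must align")

    @property
    def n_species(self) -> int:
        return int(self.module_of.size)

    def modules(self) -> list[np.ndarray]:
        """Species indices of each module, as a partition of range(N)."""
        return [
            np.flatnonzero(self.module_of == m) for m in range(self.n_modules)
        ]

    def phage_set(self, species: int) -> frozenset[tuple[int, int]]:
        """Globally-labelled (module, phage) identifiers infecting one species."""
        m = int(self.module_of[species])
        k = int(self.phage_count[species])
        return frozenset((m, p) for p in range(1, k + 1))


@dataclass
class CompatibilityMatrix:
    """One mechanism's donor->recipient compatibility matrix.

    ``entries[j, i]`` scales transfer from donor species ``j`` into recipient
    species ``i``.  ``network`` is attached for transduction matrices so the
    cross-module zero-block structure can be re-validated.
    """

    mechanism: str
    entries: np.ndarray
    species_ids: list[str] = field(default_factory=list)
    network: PhageHostNetwork | None = None

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.ndim != 2 or self.entries.shape[0] != self.entries.shape[1]:
            raise InvalidInputError("compatibility matrix must be square")
        if not self.species_ids:
            self.species_ids = default_species_ids(self.entries.shape[0])
        if len(self.species_ids) != self.entries.shape[0]:
            raise InvalidInputError("species_ids length must match matrix dimension")

    @property
    def n(self) -> int:
        return self.entries.shape[0]


@dataclass(frozen=True)
class ValidationReport:
    passed: bool
    violations: tuple[str, ...] = ()


def conjugation_alpha(
    n: int,
    spc_fraction: float = DEFAULT_SPC_FRACTION,
    attenuation: float = DEFAULT_SPC_ATTENUATION,
    rng_seed=None,
) -> CompatibilityMatrix:
    """Conjugation ruleset: super-permissive core columns at full efficiency.

    Exactly ``round(spc_fraction * n)`` recipient species are drawn uniformly
    without replacement into the super-permissive core; their columns are
    i.i.d. uniform[0, 1], all other columns i.i.d. uniform[0, 1/attenuation].
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    if not 0.0 <= spc_fraction <= 1.0:
        raise InvalidInputError("spc_fraction must be in [0, 1]")
    if attenuation < 1.0:
        raise InvalidInputError("attenuation must be >= 1")
    rng = _as_rng(rng_seed)
    n_spc = int(round(spc_fraction * n))
    spc = rng.choice(n, size=n_spc, replace=False)
    entries = rng.uniform(size=(n, n)) / attenuation
    entries[:, spc] = rng.uniform(size=(n, n_spc))
    return CompatibilityMatrix("conjugation", entries)


def transformation_alpha(
    n: int,
    p_transformable: float = DEFAULT_P_TRANSFORMABLE,
    rng_seed=None,
    ensure_nonempty: bool = True,
) -> CompatibilityMatrix:
    """Transformation ruleset: all-or-nothing transformable recipient columns.

    Each species is independently transformable with probability
    ``p_transformable``.  With ``ensure_nonempty`` (default) the draw repeats
    until at least one species is transformable, so the mechanism is never
    silently absent from a community.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    if not 0.0 <= p_transformable <= 1.0:
        raise InvalidInputError("p_transformable must be in [0, 1]")
    if ensure_nonempty and p_transformable == 0.0:
        raise ConfigurationError(
            "ensure_nonempty requires p_transformable > 0"
        )
    rng = _as_rng(rng_seed)
    while True:
        transformable = rng.uniform(size=n) < p_transformable
        if transformable.any() or not ensure_nonempty:
            break
    entries = np.zeros((n, n))
    entries[:, transformable] = 1.0
    return CompatibilityMatrix("transformation", entries)


def module_sizes_linear(n: int, n_modules: int) -> np.ndarray:
    """Module sizes proportional to 1..n_modules, summing exactly to ``n``.

    Largest-remainder rounding of the linear proportions; every module is
    forced to size >= 1 (taking from the largest modules when necessary).
    """
    if not 1 <= n_modules <= n:
        raise InvalidInputError("need 1 <= n_modules <= n")
    weights = np.arange(1, n_modules + 1, dtype=float)
    quota = n * weights / weights.sum()
    sizes = np.floor(quota).astype(int)
    remainder = n - sizes.sum()
    # stable order: largest fractional remainder first, index as tie-break
    order = np.argsort(-(quota - np.floor(quota)), kind="stable")
    sizes[order[:remainder]] += 1
    while (sizes < 1).any():
        sizes[int(np.argmin(sizes))] += 1
        sizes[int(np.argmax(sizes))] -= 1
    return sizes


def build_phage_host_network(
    n: int, n_modules: int, rng_seed=None
) -> PhageHostNetwork:
    """Draw a modular, nested phage-host network over ``n`` species.

    Module sizes follow :func:`module_sizes_linear`; species are assigned to
    modules by a uniform random permutation, and permissiveness ranks within
    each module are an independent uniform random permutation.
    """
    rng = _as_rng(rng_seed)
    sizes = module_sizes_linear(n, n_modules)
    perm = rng.permutation(n)
    module_of = np.empty(n, dtype=int)
    phage_count = np.empty(n, dtype=int)
    start = 0
    for m, s in enumerate(sizes):
        members = perm[start : start + s]
        module_of[members] = m
        phage_count[members] = rng.permutation(s) + 1
        start += s
    return PhageHostNetwork(module_of=module_of, phage_count=phage_count, n_modules=n_modules)


def transduction_alpha(network: PhageHostNetwork) -> CompatibilityMatrix:
    """Transduction ruleset from a phage-host network.

    Compatibility of donor ``d`` with recipient ``r`` is the fraction of the
    donor's phages that also infect the recipient; with nested phage sets this
    is ``min(k_d, k_r) / k_d`` inside a shared module and 0 across modules.
    """
    k = network.phage_count.astype(float)
    same_module = network.module_of[:, None] == network.module_of[None, :]
    shared = np.minimum(k[:, None], k[None, :])
    entries = np.where(same_module, shared / k[:, None], 0.0)
    return CompatibilityMatrix("transduction", entries, network=network)


def vesicle_alpha(
    n: int, rng_seed=None, participation: float = 1.0
) -> CompatibilityMatrix:
    """Vesicle-transfer ruleset: outer product of per-species efficiencies.

    Donor and recipient efficiencies are i.i.d. uniform[0, 1].  When
    ``participation < 1`` a uniformly chosen complement of
    ``round(participation * n)`` species neither produces nor takes up
    vesicles (both efficiencies zeroed), modelling communities where vesicle
    exchange is not universal.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    if not 0.0 <= participation <= 1.0:
        raise InvalidInputError("participation must be in [0, 1]")
    rng = _as_rng(rng_seed)
    donor_eff = rng.uniform(size=n)
    recip_eff = rng.uniform(size=n)
    if participation < 1.0:
        n_out = n - int(round(participation * n))
        out = rng.choice(n, size=n_out, replace=False)
        donor_eff[out] = 0.0
        recip_eff[out] = 0.0
    return CompatibilityMatrix("vesicle", np.outer(donor_eff, recip_eff))


def validate_alpha(matrix: CompatibilityMatrix) -> ValidationReport:
    """Structural validation of a compatibility matrix.

    Checks squareness, the [0, 1] entry range and, when a phage-host network
    is attached, that every cross-module entry is zero.  Returns a report
    rather than raising so callers can surface all violations at once.
    """
    violations: list[str] = []
    entries = matrix.entries
    if entries.ndim != 2 or entries.shape[0] != entries.shape[1]:
        violations.append(f"matrix is not square: shape {entries.shape}")
    else:
        bad = np.argwhere((entries < 0.0) | (entries > 1.0) | ~np.isfinite(entries))
        for j, i in bad[:20]:
            violations.append(
                f"entry ({j}, {i}) = {entries[j, i]!r} outside [0, 1]"
            )
        if matrix.network is not None:
            cross = matrix.network.module_of[:, None] != matrix.network.module_of[None, :]
            nonzero_cross = np.argwhere(cross & (entries != 0.0))
            for j, i in nonzero_cross[:20]:
                violations.append(
                    f"cross-module entry ({j}, {i}) = {entries[j, i]!r} must be 0"
                )
    return ValidationReport(passed=not violations, violations=tuple(violations))
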