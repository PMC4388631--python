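"""Model and chain I/O.

Stoichiometric models are read either from SBML (Level 3 + FBC, through
cobrapy) or from a plain tab-separated stoichiometry table whose header row
carries reaction ids and whose first column carries metabolite ids, with a
companion bounds table of ``reaction_id <TAB> lower <TAB> upper`` rows.  The
table dialect accepts ``#`` comment lines so that toy models can be written
inline in tests.

Sample chains, polytopes and ellipsoids all share one diffable text
container: a ``#fluxhr`` header line holding a JSON metadata object, followed
by one or more ``#section <name>`` blocks of tab-separated numbers written at
full float precision (``%.17g``, which round-trips IEEE doubles bitwise).
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ModelFormatError, ModelValidationError

logger = logging.getLogger(__name__)

#: Bound substituted (with a warning) when a reaction has no explicit bound.
#: The sampled polytopes must be bounded; unbounded rays are out of scope.
DEFAULT_BIG_BOUND = 1.0e6

_FLOAT_FMT = "%.17g"
_HEADER_PREFIX = "#fluxhr"
_SECTION_PREFIX = "#section"


@dataclass
class StoichiometricModel:
    """A named stoichiometric matrix with per-reaction flux bounds.

    Parameters
    ----------
    metabolite_ids : list of str
        Row labels of ``S`` (length M).
    reaction_ids : list of str
        Column labels of ``S`` (length N).
    S : (M, N) ndarray
        Stoichiometric coefficients (dimensionless).
    lower_bounds, upper_bounds : (N,) ndarray
        Flux bounds in the model's flux units (e.g. mmol/gDW/h).
    """

    metabolite_ids: list
    reaction_ids: list
    S: np.ndarray
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        M, N = self.S.shape
        if len(self.metabolite_ids) != M:
            raise ModelValidationError(
                f"S has {M} rows but {len(self.metabolite_ids)} metabolite ids"
            )
        if len(self.reaction_ids) != N:
            raise ModelValidationError(
                f"S has {N} columns but {len(self.reaction_ids)} reaction ids"
            )
        if len(set(self.reaction_ids)) != N:
            raise ModelValidationError("duplicate reaction ids")
        if len(set(self.metabolite_ids)) != M:
            raise ModelValidationError("duplicate metabolite ids")
        if self.lower_bounds.shape != (N,) or self.upper_bounds.shape != (N,):
            raise ModelValidationError("bounds vectors must have length N")
        bad = np.nonzero(self.lower_bounds > self.upper_bounds)[0]
        if bad.size:
            rid = self.reaction_ids[bad[0]]
            raise ModelValidationError(
                f"lower bound exceeds upper bound for reaction {rid!r}"
            )

    @property
    def n_metabolites(self) -> int:
        return self.S.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.S.shape[1]


# ---------------------------------------------------------------------------
# model reading / writing
# ---------------------------------------------------------------------------

def read_model(path, format: str = "table", bounds_path=None) -> StoichiometricModel:
    """Read a stoichiometric model from disk.

    Parameters
    ----------
    path : path-like
        The stoichiometry table (``format='table'``) or SBML file.
    format : {'table', 'sbml'}
    bounds_path : path-like, optional
        Companion bounds table for the table format.  Defaults to
        ``<stem>.bounds.tsv`` next to *path*; reactions absent from the
        bounds table fall back to ``(-DEFAULT_BIG_BOUND, +DEFAULT_BIG_BOUND)``
        with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "table":
        return _read_table_model(path, bounds_path)
    if format == "sbml":
        return _read_sbml_model(path)
    raise ValueError(f"unknown model format {format!r}")


def _read_table_model(path: Path, bounds_path) -> StoichiometricModel:
    lines = [
        ln for ln in path.read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise ModelFormatError(f"{path}: empty stoichiometry table")
    header = lines[0].split("\t")
    reaction_ids = [c.strip() for c in header[1:]]
    if not reaction_ids:
        raise ModelFormatError(f"{path}: header row has no reaction ids")
    metabolite_ids, rows = [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != len(reaction_ids) + 1:
            raise ModelFormatError(
                f"{path}:{lineno}: expected {len(reaction_ids) + 1} columns, "
                f"got {len(cells)}"
            )
        metabolite_ids.append(cells[0].strip())
        try:
            rows.append([float(c) for c in cells[1:]])
        except ValueError as exc:
            raise ModelFormatError(f"{path}:{lineno}: non-numeric entry ({exc})")
    S = np.array(rows, dtype=float)

    if bounds_path is None:
        candidate = Path(str(path).rsplit(".", 1)[0] + ".bounds.tsv")
        bounds_path = candidate if candidate.exists() else None
    lb = np.full(len(reaction_ids), -DEFAULT_BIG_BOUND)
    ub = np.full(len(reaction_ids), DEFAULT_BIG_BOUND)
    seen = set()
    if bounds_path is not None:
        bpath = Path(bounds_path)
        if not bpath.exists():
            raise FileNotFoundError(bpath)
        for lineno, ln in enumerate(bpath.read_text().splitlines(), start=1):
            if not ln.strip() or ln.lstrip().startswith("#"):
                continue
            cells = [c.strip() for c in ln.replace(",", "\t").split("\t") if c.strip()]
            if len(cells) != 3:
                raise ModelFormatError(
                    f"{bpath}:{lineno}: expected 'reaction<TAB>lower<TAB>upper'"
                )
            rid, lo, hi = cells
            if rid not in reaction_ids:
                raise ModelFormatError(f"{bpath}:{lineno}: unknown reaction {rid!r}")
            i = reaction_ids.index(rid)
            try:
                lb[i], ub[i] = float(lo), float(hi)
            except ValueError as exc:
                raise ModelFormatError(f"{bpath}:{lineno}: non-numeric bound ({exc})")
            seen.add(rid)
    missing = [r for r in reaction_ids if r not in seen]
    if missing:
        logger.warning(
            "no bounds for %d reaction(s) (%s...); using +/-%g",
            len(missing), missing[0], DEFAULT_BIG_BOUND,
        )
    return StoichiometricModel(metabolite_ids, reaction_ids, S, lb, ub)


def _read_sbml_model(path: Path) -> StoichiometricModel:
    try:
        import cobra
        from cobra.util.array import create_stoichiometric_matrix
    except ImportError as exc:  # pragma: no cover
        raise ModelFormatError(
            "SBML support requires the optional dependency 'cobra'"
        ) from exc
    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:
        raise ModelFormatError(f"{path}: SBML parse failure: {exc}") from exc
    S = create_stoichiometric_matrix(cm)
    metabolite_ids = [m.id for m in cm.metabolites]
    reaction_ids = [r.id for r in cm.reactions]
    lb = np.array([r.lower_bound for r in cm.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in cm.reactions], dtype=float)
    nofin = ~np.isfinite(lb)
    if nofin.any():
        logger.warning("replacing %d infinite lower bounds by -%g",
                       nofin.sum(), DEFAULT_BIG_BOUND)
        lb[nofin] = -DEFAULT_BIG_BOUND
    nofin = ~np.isfinite(ub)
    if nofin.any():
        logger.warning("replacing %d infinite upper bounds by +%g",
                       nofin.sum(), DEFAULT_BIG_BOUND)
        ub[nofin] = DEFAULT_BIG_BOUND
    return StoichiometricModel(metabolite_ids, reaction_ids, S, lb, ub)


def write_model(model: StoichiometricModel, path, bounds_path=None) -> None:
    """Write *model* in the plain-table dialect (plus a bounds table)."""
    path = Path(path)
    if bounds_path is None:
        bounds_path = Path(str(path).rsplit(".", 1)[0] + ".bounds.tsv")
    with open(path, "w") as fh:
        fh.write("metabolite\t" + "\t".join(model.reaction_ids) + "\n")
        for mid, row in zip(model.metabolite_ids, model.S):
            fh.write(mid + "\t" + "\t".join(_FLOAT_FMT % v for v in row) + "\n")
    with open(bounds_path, "w") as fh:
        fh.write("# reaction\tlower\tupper\n")
        for rid, lo, hi in zip(model.reaction_ids, model.lower_bounds,
                               model.upper_bounds):
            fh.write(f"{rid}\t{_FLOAT_FMT % lo}\t{_FLOAT_FMT % hi}\n")


# ---------------------------------------------------------------------------
# generic TSV container (chains, polytopes, ellipsoids, reports)
# ---------------------------------------------------------------------------

def write_container(path, kind: str, sections: dict, meta: dict | None = None) -> None:
    """Write named numeric arrays plus JSON metadata to one text file."""
    meta = dict(meta or {})
    meta["kind"] = kind
    with open(path, "w") as fh:
        fh.write(f"{_HEADER_PREFIX} {json.dumps(meta)}\n")
        for name, arr in sections.items():
            arr = np.atleast_2d(np.asarray(arr, dtype=float))
            fh.write(f"{_SECTION_PREFIX} {name}\n")
            np.savetxt(fh, arr, fmt=_FLOAT_FMT, delimiter="\t")


def read_container(path):
    """Read a container written by :func:`write_container`.

    Returns
    -------
    (meta, sections) : dict, dict of ndarray
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(_HEADER_PREFIX):
            raise ModelFormatError(f"{path}: missing '{_HEADER_PREFIX}' header")
        meta = json.loads(first[len(_HEADER_PREFIX):])
        sections, name, buf = {}, None, []
        def _flush():
            if name is not None:
                sections[name] = np.loadtxt(io.StringIO("".join(buf)), ndmin=2)
        for ln in fh:
            if ln.startswith(_SECTION_PREFIX):
                _flush()
                name = ln[len(_SECTION_PREFIX):].strip()
                buf = []
            else:
                buf.append(ln)
        _flush()
    return meta, sections


def write_chain(chain, path) -> None:
    """Write a :class:`~fluxhr.samplers.SampleChain` losslessly to TSV."""
    if chain.points.shape[0] == 0:
        raise ValueError("refusing to write an empty chain")
    meta = {
        "sampler_id": chain.sampler_id,
        "seed": chain.seed,
        "thinning": chain.thinning,
        "labels": chain.labels,
        "ellipsoid_ref": chain.ellipsoid_ref,
        "n_resampled": chain.n_resampled,
    }
    write_container(path, "chain", {"points": chain.points}, meta)


def read_chain(path):
    """Read a chain written by :func:`write_chain`."""
    from .samplers import SampleChain  # deferred: avoids an import cycle

    meta, sections = read_container(path)
    if meta.get("kind") != "chain":
        raise ModelFormatError(f"{path}: not a chain container")
    return SampleChain(
        points=sections["points"],
        sampler_id=meta["sampler_id"],
        seed=meta["seed"],
        thinning=meta["thinning"],
        labels=meta.get("labels"),
        ellipsoid_ref=meta.get("ellipsoid_ref"),
        n_resampled=meta.get("n_resampled", 0),
    )


def write_polytope(poly, path) -> None:
    sections = {
        "anchor": poly.anchor, "basis": poly.basis, "G": poly.G, "h": poly.h,
    }
    write_container(path, "polytope", sections, {"labels": poly.labels})


def read_polytope(path):
    from .polytope import Polytope  # deferred: avoids an import cycle

    meta, sections = read_container(path)
    if meta.get("kind") != "polytope":
        raise ModelFormatError(f"{path}: not a polytope container")
    return Polytope(
        anchor=sections["anchor"].ravel(),
        basis=sections["basis"],
        G=sections["G"],
        h=sections["h"].ravel(),
        labels=meta.get("labels"),
    )


def write_ellipsoid(ell, path, meta: dict | None = None) -> None:
    write_container(path, "ellipsoid",
                    {"center": ell.center, "shape": ell.shape}, meta)


def read_ellipsoid(path):
    from .rounding import Ellipsoid  # deferred: avoids an import cycle

    meta, sections = read_container(path)
    if meta.get("kind") != "ellipsoid":
        raise ModelFormatError(f"{path}: not an ellipsoid container")
    return Ellipsoid(center=sections["center"].ravel(), shape=sections["shape"])
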