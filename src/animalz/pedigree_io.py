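"""Reading, validation and ordering of pedigrees and phenotype tables.

A pedigree is the backbone of every relationship-matrix computation in this
package: an ordered set of individuals with optional sire/dam links, a sex
for everyone (required for the sex-linked matrix Z), and an optional hatch
cohort.  Individuals are stored topologically ordered (parents before
offspring), which is what every downstream recursion assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

FEMALE = "female"
MALE = "male"

#: accepted spellings for each sex in input files
DEFAULT_SEX_MAP = {
    "f": FEMALE, "female": FEMALE, "1": FEMALE, "w": FEMALE,
    "m": MALE, "male": MALE, "2": MALE, "z": MALE,
}

DEFAULT_MISSING_CODES = ("", "0", "na", "nan", ".")


class PedigreeError(ValueError):
    """A hard violation of the pedigree contract (cycle, sex conflict, ...)."""


class PhenotypeError(ValueError):
    """A hard violation of the phenotype-table contract."""


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    Parameters refer to positions in the ordered arrays; ``sire`` and ``dam``
    hold the position of the parent or -1 when unknown.  ``heterogametic_sex``
    selects the sex-chromosome system: ``"female"`` is the avian ZW case
    (females carry a single Z), ``"male"`` the mammalian XY case.
    """

    ids: np.ndarray            # unicode array, ordered
    sire: np.ndarray           # int64 positions, -1 = unknown
    dam: np.ndarray            # int64 positions, -1 = unknown
    sex: np.ndarray            # unicode array of "female"/"male"
    cohort: np.ndarray | None = None   # float array, NaN = unknown
    heterogametic_sex: str = FEMALE
    input_order: np.ndarray | None = None  # original row of each ordered individual

    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.sex = np.asarray(self.sex, dtype=object)
        if self.cohort is not None:
            self.cohort = np.asarray(self.cohort, dtype=float)
        if self.heterogametic_sex not in (FEMALE, MALE):
            raise PedigreeError(
                f"heterogametic_sex must be 'female' or 'male', got {self.heterogametic_sex!r}")
        self._index = {iid: k for k, iid in enumerate(self.ids)}

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def is_male(self) -> np.ndarray:
        return self.sex == MALE

    @property
    def is_female(self) -> np.ndarray:
        return self.sex == FEMALE

    @property
    def n_male(self) -> int:
        return int(np.sum(self.is_male))

    @property
    def n_female(self) -> int:
        return int(np.sum(self.is_female))

    def index_of(self, iid) -> int:
        return self._index[iid]

    def founders(self) -> np.ndarray:
        return np.flatnonzero((self.sire < 0) & (self.dam < 0))

    def generation_depth(self) -> np.ndarray:
        """0 for founders, 1 + max(parent depth) otherwise."""
        depth = np.zeros(self.n, dtype=np.int64)
        for i in range(self.n):
            d = 0
            if self.sire[i] >= 0:
                d = depth[self.sire[i]] + 1
            if self.dam[i] >= 0:
                d = max(d, depth[self.dam[i]] + 1)
            depth[i] = d
        return depth

    def to_frame(self) -> pd.DataFrame:
        """Pedigree as a DataFrame (parent columns hold ids, '' = unknown)."""
        def pid(arr):
            return [self.ids[p] if p >= 0 else "" for p in arr]
        out = pd.DataFrame({
            "id": self.ids, "sire": pid(self.sire), "dam": pid(self.dam),
            "sex": self.sex,
        })
        if self.cohort is not None:
            out["cohort"] = [("" if np.isnan(c) else int(c)) for c in self.cohort]
        return out

    def write(self, path, sep=",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


@dataclass
class PhenotypeTable:
    """Phenotypes aligned to a pedigree.

    ``data`` has one row per pedigree individual, in pedigree order, with a
    ``y`` column (NaN = not phenotyped) plus any covariate columns.
    """

    data: pd.DataFrame
    standardization: tuple | None = None  # (mean, sd) applied, if any

    @property
    def y(self) -> np.ndarray:
        return self.data["y"].to_numpy(dtype=float)

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask over pedigree positions: phenotype present."""
        return ~np.isnan(self.y)

    @property
    def n_d(self) -> int:
        return int(self.observed.sum())

    def write(self, path, sep=",") -> None:
        out = self.data.reset_index().rename(columns={"index": "id"})
        out.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# construction and reading

def pedigree_from_records(records, heterogametic_sex=FEMALE,
                          auto_add_parents=True, warnings_out=None) -> Pedigree:
    """Validate and topologically order raw pedigree records.

    ``records``: iterable of (id, sire_id_or_None, dam_id_or_None, sex, cohort_or_None).
    Individuals appearing only as parents are auto-added as founders (sires as
    males, dams as females) with a warning, a common situation in field data.
    """
    warnings_out = warnings_out if warnings_out is not None else []
    rows = [(str(r[0]), None if r[1] is None else str(r[1]),
             None if r[2] is None else str(r[2]), r[3], r[4]) for r in records]

    seen = {}
    for row in rows:
        if row[0] in seen:
            raise PedigreeError(f"duplicate individual id {row[0]!r}")
        seen[row[0]] = row

    as_sire = {r[1] for r in rows if r[1] is not None}
    as_dam = {r[2] for r in rows if r[2] is not None}
    both = as_sire & as_dam
    if both:
        raise PedigreeError(
            f"individual(s) recorded as both sire and dam: {sorted(both)}")

    for pid in sorted(as_sire | as_dam):
        if pid not in seen:
            if not auto_add_parents:
                raise PedigreeError(f"unknown parent id {pid!r}")
            sex = MALE if pid in as_sire else FEMALE
            warnings_out.append(
                f"parent {pid!r} not listed as an individual; added as {sex} founder")
            rows.append((pid, None, None, sex, None))
            seen[pid] = rows[-1]

    for iid, sid, did, sex, _ in rows:
        if sex not in (FEMALE, MALE):
            raise PedigreeError(f"individual {iid!r} has missing or invalid sex {sex!r}")
    for iid, sid, did, _, _ in rows:
        if sid is not None and seen[sid][3] != MALE:
            raise PedigreeError(f"sire {sid!r} of {iid!r} is not recorded as male")
        if did is not None and seen[did][3] != FEMALE:
            raise PedigreeError(f"dam {did!r} of {iid!r} is not recorded as female")
        if sid == iid or did == iid:
            raise PedigreeError(f"individual {iid!r} is its own parent")

    # topological order via parent links; cycle -> error naming a member
    g = nx.DiGraph()
    g.add_nodes_from(r[0] for r in rows)
    for iid, sid, did, _, _ in rows:
        if sid is not None:
            g.add_edge(sid, iid)
        if did is not None:
            g.add_edge(did, iid)
    try:
        cyc = nx.find_cycle(g)
        raise PedigreeError(f"pedigree contains an ancestry cycle through {cyc[0][0]!r}")
    except nx.NetworkXNoCycle:
        pass

    input_pos = {r[0]: k for k, r in enumerate(rows)}
    # stable order: lexicographic toposort keyed by original file position
    order = list(nx.lexicographical_topological_sort(g, key=lambda v: input_pos[v]))
    pos = {iid: k for k, iid in enumerate(order)}

    n = len(order)
    ids = np.array(order, dtype=object)
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    sex = np.empty(n, dtype=object)
    cohort = np.full(n, np.nan)
    any_cohort = False
    for iid in order:
        _, sid, did, sx, co = seen[iid]
        k = pos[iid]
        sex[k] = sx
        if sid is not None:
            sire[k] = pos[sid]
        if did is not None:
            dam[k] = pos[did]
        if co is not None and not (isinstance(co, float) and np.isnan(co)):
            cohort[k] = float(co)
            any_cohort = True
    ped = Pedigree(ids=ids, sire=sire, dam=dam, sex=sex,
                   cohort=cohort if any_cohort else None,
                   heterogametic_sex=heterogametic_sex,
                   input_order=np.array([input_pos[i] for i in order]))
    return ped


def _read_table(path, sep):
    if sep is None:
        # sniff comma vs tab from the header line
        import os
        if isinstance(path, (str, bytes, os.PathLike)):
            with open(path) as fh:
                head = fh.readline()
        else:
            head = path.readline()
            path.seek(0)
        sep = "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_pedigree(path, sep=None, id_col="id", sire_col="sire", dam_col="dam",
                  sex_col="sex", cohort_col="cohort",
                  missing_codes=DEFAULT_MISSING_CODES, sex_map=None,
                  heterogametic_sex=FEMALE, warnings_out=None) -> Pedigree:
    """Read a delimited pedigree file and return an ordered, validated Pedigree.

    Missing parents may be coded as an empty field or "0" (configurable).
    Sexes accept F/M, female/male, 1/2 (configurable via ``sex_map``).
    """
    df = _read_table(path, sep)
    for col in (id_col, sire_col, dam_col, sex_col):
        if col not in df.columns:
            raise PedigreeError(f"required column {col!r} not found in pedigree file")
    smap = dict(DEFAULT_SEX_MAP if sex_map is None else sex_map)
    missing = {str(c).lower() for c in missing_codes}

    def parent(v):
        v = v.strip()
        return None if v.lower() in missing else v

    records = []
    for _, row in df.iterrows():
        iid = row[id_col].strip()
        if iid.lower() in missing:
            raise PedigreeError("blank individual id in pedigree file")
        sx_raw = row[sex_col].strip().lower()
        sx = smap.get(sx_raw)
        co = None
        if cohort_col in df.columns:
            c = row[cohort_col].strip()
            if c.lower() not in missing:
                co = float(c)
        records.append((iid, parent(row[sire_col]), parent(row[dam_col]), sx, co))
    return pedigree_from_records(records, heterogametic_sex=heterogametic_sex,
                                 warnings_out=warnings_out)


@dataclass
class PedigreeReport:
    n: int
    n_founders: int
    n_female: int
    n_male: int
    max_generation_depth: int
    cohorts: dict
    warnings: list


def validate_pedigree(ped: Pedigree) -> PedigreeReport:
    """Summarize a pedigree: founders, sex counts, depth, cohort sizes.

    Hard violations are enforced at construction; this reports bookkeeping
    plus soft warnings.
    """
    warnings = []
    if ped.n_female == 0 or ped.n_male == 0:
        warnings.append("single-sex pedigree: sex-linked variance is only weakly "
                        "identifiable from within-sex covariances")
    cohorts = {}
    if ped.cohort is not None:
        ok = ~np.isnan(ped.cohort)
        vals, counts = np.unique(ped.cohort[ok].astype(int), return_counts=True)
        cohorts = dict(zip(vals.tolist(), counts.tolist()))
        if (~ok).any():
            warnings.append(f"{int((~ok).sum())} individuals lack a cohort")
    return PedigreeReport(
        n=ped.n, n_founders=len(ped.founders()),
        n_female=ped.n_female, n_male=ped.n_male,
        max_generation_depth=int(ped.generation_depth().max(initial=0)),
        cohorts=cohorts, warnings=warnings,
    )


def read_phenotypes(path, ped: Pedigree, sep=None, id_col="id", y_col="y",
                    missing_codes=DEFAULT_MISSING_CODES) -> PhenotypeTable:
    """Read a delimited phenotype file and align it to the pedigree.

    Pedigree members absent from the file are kept as missing-phenotype rows.
    Extra columns are carried along as covariates.
    """
    df = _read_table(path, sep)
    for col in (id_col, y_col):
        if col not in df.columns:
            raise PhenotypeError(f"required column {col!r} not found in phenotype file")
    missing = {str(c).lower() for c in missing_codes}

    seen = set()
    y = np.full(ped.n, np.nan)
    covs = {c: np.full(ped.n, np.nan, dtype=object)
            for c in df.columns if c not in (id_col, y_col)}
    for _, row in df.iterrows():
        iid = row[id_col].strip()
        if iid not in ped._index:
            raise PhenotypeError(f"phenotyped individual {iid!r} is not in the pedigree")
        if iid in seen:
            raise PhenotypeError(f"duplicate phenotype row for {iid!r}")
        seen.add(iid)
        k = ped.index_of(iid)
        v = row[y_col].strip()
        if v.lower() not in missing:
            y[k] = float(v)
        for c in covs:
            cv = row[c].strip()
            if cv.lower() not in missing:
                covs[c][k] = cv
    data = pd.DataFrame({"y": y}, index=pd.Index(ped.ids, name="id"))
    for c, v in covs.items():
        data[c] = v
    return PhenotypeTable(data=data)


def phenotypes_from_arrays(ped: Pedigree, y: np.ndarray, **covariates) -> PhenotypeTable:
    """Build a PhenotypeTable from arrays already in pedigree order."""
    y = np.asarray(y, dtype=float)
    if y.shape != (ped.n,):
        raise PhenotypeError(f"y has shape {y.shape}, expected ({ped.n},)")
    data = pd.DataFrame({"y": y}, index=pd.Index(ped.ids, name="id"))
    for name, v in covariates.items():
        data[name] = np.asarray(v)
    return PhenotypeTable(data=data)


def standardize_trait(tab: PhenotypeTable) -> PhenotypeTable:
    """Center and scale the trait to mean 0, variance 1 over phenotyped individuals.

    The standardization is pooled across the sexes.  Within-sex standardization
    is deliberately not offered: rescaling each sex separately distorts the
    sex-linked covariance structure the Z matrix encodes, so it is inconsistent
    with a sex-linked animal model.
    """
    y = tab.y
    obs = tab.observed
    if obs.sum() < 2:
        raise PhenotypeError("standardization needs at least 2 phenotyped individuals")
    mean = float(np.mean(y[obs]))
    sd = float(np.std(y[obs]))  # population sd: result has variance exactly 1
    if sd == 0.0:
        raise PhenotypeError("trait has zero variance; cannot standardize")
    data = tab.data.copy()
    data["y"] = (y - mean) / sd
    return PhenotypeTable(data=data, standardization=(mean, sd))
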