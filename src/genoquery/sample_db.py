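"""PED parsing and the sample database.

The PED dialect is a tab-separated table whose first line is a header
naming at least IndividualID plus, depending on use, Phenotype (pedigree /
case-control filtering) or Population and Sex (population filtering).
Phenotype codes: 0 = exclude from every analysis, 1 = unaffected
(control), 2 = affected offspring (case), 3 = affected or carrier parent.
Sex: 1 = male, 2 = female, NA = unavailable.

The sample database joins the PED attributes to index column positions and
is persisted as a single SQLite table.  Index samples absent from the PED
are recorded with Phenotype 0 so they never enter a selection or a MAF
denominator.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .wah_index import GenotypeIndex

VALID_PHENOTYPES = {0, 1, 2, 3}


class PedError(ValueError):
    """Invalid PED content or sample-database mismatch."""


@dataclass(frozen=True)
class PedRow:
    individual_id: str
    phenotype: int
    sex: int | None  # 1 male, 2 female, None unavailable
    population: str | None


@dataclass
class PedTable:
    rows: list[PedRow]
    has_phenotype: bool
    has_sex: bool
    has_population: bool

    def __len__(self) -> int:
        return len(self.rows)


def _parse_sex(raw: object) -> int | None:
    text = str(raw).strip()
    if text in ("", "NA", "nan", "None", "."):
        return None
    try:
        sex = int(float(text))
    except ValueError:
        raise PedError(f"invalid Sex value {text!r} (expected 1, 2 or NA)")
    if sex not in (1, 2):
        raise PedError(f"invalid Sex value {text!r} (expected 1, 2 or NA)")
    return sex


def parse_ped(path: str | Path) -> PedTable:
    """Read and validate a PED file (header case-insensitive, extra
    columns carried but ignored)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    colmap = {c.lower(): c for c in df.columns}
    if "individualid" not in colmap:
        raise PedError(f"{path}: PED header must name IndividualID")
    has_phenotype = "phenotype" in colmap
    has_sex = "sex" in colmap
    has_population = "population" in colmap
    if not has_phenotype and not (has_sex and has_population):
        raise PedError(
            f"{path}: PED header must name Phenotype (pedigree/case-control "
            "use) or Population and Sex (population use)"
        )

    rows: list[PedRow] = []
    seen: set[str] = set()
    for i, rec in enumerate(df.to_dict("records"), start=2):  # 1-based + header
        iid = str(rec[colmap["individualid"]]).strip()
        if not iid:
            raise PedError(f"{path}: row {i}: empty IndividualID")
        if iid in seen:
            raise PedError(f"{path}: row {i}: duplicate IndividualID {iid!r}")
        seen.add(iid)
        if has_phenotype:
            raw = str(rec[colmap["phenotype"]]).strip()
            try:
                phen = int(raw)
            except ValueError:
                raise PedError(
                    f"{path}: row {i}: Phenotype {raw!r} is not an integer"
                ) from None
            if phen not in VALID_PHENOTYPES:
                raise PedError(
                    f"{path}: row {i}: Phenotype {phen} outside "
                    f"{sorted(VALID_PHENOTYPES)}"
                )
        else:
            phen = 1
        sex = _parse_sex(rec[colmap["sex"]]) if has_sex else None
        pop_raw = str(rec[colmap["population"]]).strip() if has_population else ""
        population = pop_raw if pop_raw not in ("", "NA") else None
        rows.append(PedRow(iid, phen, sex, population))
    return PedTable(rows, has_phenotype, has_sex, has_population)


@dataclass(frozen=True)
class SampleEntry:
    name: str
    position: int  # column in the genotype index
    phenotype: int
    sex: int | None
    population: str | None


class SampleDB:
    """Sample roster keyed by name, ordered by index column position."""

    def __init__(self, entries: Sequence[SampleEntry], has_phenotype: bool = True):
        self.entries = sorted(entries, key=lambda e: e.position)
        self.has_phenotype = has_phenotype
        self._by_name = {e.name: e for e in self.entries}
        if len(self._by_name) != len(self.entries):
            raise PedError("duplicate sample names in database")

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str) -> SampleEntry:
        try:
            return self._by_name[name]
        except KeyError:
            raise PedError(f"sample {name!r} not in database") from None

    def select(
        self,
        phenotype: Iterable[int] | None = None,
        population: str | None = None,
        sex: int | None = None,
        names: Iterable[str] | None = None,
    ) -> list[str]:
        """Samples matching the intersection of the given predicates.

        Phenotype-0 samples are always excluded; order is stable by index
        position.
        """
        phen_set = set(phenotype) if phenotype is not None else None
        name_set = set(names) if names is not None else None
        if name_set is not None:
            unknown = name_set - set(self._by_name)
            if unknown:
                raise PedError(
                    f"sample(s) not in database: {', '.join(sorted(unknown))}"
                )
        out = []
        for e in self.entries:
            if e.phenotype == 0:
                continue
            if phen_set is not None and e.phenotype not in phen_set:
                continue
            if population is not None and e.population != population:
                continue
            if sex is not None and e.sex != sex:
                continue
            if name_set is not None and e.name not in name_set:
                continue
            out.append(e.name)
        return out

    def populations(self) -> list[str]:
        return sorted(
            {e.population for e in self.entries if e.population is not None}
        )

    # -- persistence (single SQLite table, the roster) --------------------

    def save(self, path: str | Path) -> None:
        con = sqlite3.connect(path)
        try:
            con.execute("DROP TABLE IF EXISTS samples")
            con.execute(
                "CREATE TABLE samples ("
                "name TEXT PRIMARY KEY, position INTEGER NOT NULL, "
                "phenotype INTEGER NOT NULL, sex INTEGER, population TEXT)"
            )
            con.execute("DROP TABLE IF EXISTS meta")
            con.execute("CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT)")
            con.execute(
                "INSERT INTO meta VALUES ('has_phenotype', ?)",
                ("1" if self.has_phenotype else "0",),
            )
            con.executemany(
                "INSERT INTO samples VALUES (?,?,?,?,?)",
                [
                    (e.name, e.position, e.phenotype, e.sex, e.population)
                    for e in self.entries
                ],
            )
            con.commit()
        finally:
            con.close()

    @classmethod
    def load(cls, path: str | Path) -> "SampleDB":
        if not Path(path).exists():
            raise PedError(f"sample database {path} does not exist")
        con = sqlite3.connect(path)
        try:
            try:
                rows = con.execute(
                    "SELECT name, position, phenotype, sex, population "
                    "FROM samples ORDER BY position"
                ).fetchall()
                meta = dict(con.execute("SELECT key, value FROM meta").fetchall())
            except sqlite3.DatabaseError as exc:
                raise PedError(f"{path}: not a sample database") from exc
        finally:
            con.close()
        entries = [
            SampleEntry(name, pos, phen, sex, population)
            for name, pos, phen, sex, population in rows
        ]
        return cls(entries, has_phenotype=meta.get("has_phenotype", "1") == "1")


def create_sample_db(ped: PedTable, index: GenotypeIndex) -> SampleDB:
    """Join PED attributes to index columns.

    Every PED individual must exist in the index; index samples missing
    from the PED become Phenotype-0 entries (excluded everywhere).
    """
    index_names = index.sample_names
    positions = {name: i for i, name in enumerate(index_names)}
    missing = [r.individual_id for r in ped.rows if r.individual_id not in positions]
    if missing:
        raise PedError(f"sample(s) not in index: {', '.join(missing)}")
    entries = [
        SampleEntry(
            r.individual_id,
            positions[r.individual_id],
            r.phenotype,
            r.sex,
            r.population,
        )
        for r in ped.rows
    ]
    in_ped = {r.individual_id for r in ped.rows}
    for name, pos in positions.items():
        if name not in in_ped:
            entries.append(SampleEntry(name, pos, 0, None, None))
    return SampleDB(entries, has_phenotype=ped.has_phenotype)
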