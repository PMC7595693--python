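"""Relational persistence of objects, distances, and derived measurements.

The backend is an embedded SQLite database file: zero-configuration, a
single portable artifact per analysis, and the same SQL semantics as a
server-based backend for every query the pipeline issues.  One object
table is created per structure (``objects_<structure>``); distances,
molecule estimates, profiles, and run provenance live in shared tables.

Surface and member voxel coordinates are stored as one zlib-compressed
int32 blob per object rather than one row per voxel — large organelles
can have tens of thousands of surface voxels.  CSV export encodes those
blobs as base64 so the exported table round-trips losslessly through
:meth:`ObjectStore.import_csv`.

Backups use the backend's native SQL dump; restoring the dump into a
fresh store reproduces every table exactly.
"""

from __future__ import annotations

import base64
import sqlite3
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from .distances import DistanceRecord
from .extraction import SubcellularObject
from .quantify import DistributionProfile, MoleculeEstimate

__all__ = ["ObjectStore"]


def _pack(coords: np.ndarray | None) -> bytes | None:
    if coords is None:
        return None
    return zlib.compress(np.ascontiguousarray(coords, dtype=np.int32).tobytes())


def _unpack(blob: bytes | None) -> np.ndarray | None:
    if blob is None:
        return None
    return np.frombuffer(zlib.decompress(blob), dtype=np.int32).reshape(-1, 3).copy()


def _table_name(structure: str) -> str:
    safe = "".join(ch if ch.isalnum() or ch == "_" else "_" for ch in structure.lower())
    if not safe or not (safe[0].isalpha() or safe[0] == "_"):
        raise ValueError(f"invalid structure name {structure!r}")
    return f"objects_{safe}"


_OBJECT_COLUMNS = (
    "image_id, object_id, total_intensity, volume_voxels, "
    "centroid_x, centroid_y, centroid_z, surface_coords, voxel_coords"
)


class ObjectStore:
    """SQLite-backed store for the pipeline's tables.

    Use as a context manager or call :meth:`close` explicitly.
    """

    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.execute("PRAGMA foreign_keys = ON")
        self._init_schema()

    def __enter__(self) -> "ObjectStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def close(self) -> None:
        self.conn.commit()
        self.conn.close()

    def _init_schema(self) -> None:
        cur = self.conn.cursor()
        cur.execute(
            """CREATE TABLE IF NOT EXISTS distances (
                image_id TEXT NOT NULL,
                structure_pair TEXT NOT NULL,
                object_id INTEGER NOT NULL,
                target_object_id INTEGER NOT NULL,
                distance_um REAL NOT NULL CHECK (distance_um >= 0),
                method TEXT NOT NULL,
                PRIMARY KEY (image_id, structure_pair, object_id)
            )"""
        )
        cur.execute(
            """CREATE TABLE IF NOT EXISTS measurements (
                image_id TEXT NOT NULL,
                structure TEXT NOT NULL,
                object_id INTEGER NOT NULL,
                molecules REAL NOT NULL,
                is_granule INTEGER NOT NULL,
                PRIMARY KEY (image_id, structure, object_id)
            )"""
        )
        cur.execute(
            """CREATE TABLE IF NOT EXISTS profiles (
                image_id TEXT NOT NULL,
                structure_pair TEXT NOT NULL,
                distance_um REAL NOT NULL,
                cumulative_percent REAL NOT NULL,
                weight_mode TEXT NOT NULL,
                PRIMARY KEY (image_id, structure_pair, distance_um, weight_mode)
            )"""
        )
        cur.execute(
            """CREATE TABLE IF NOT EXISTS runs (
                run_id INTEGER PRIMARY KEY AUTOINCREMENT,
                stage TEXT NOT NULL,
                image_id TEXT NOT NULL,
                params_json TEXT NOT NULL
            )"""
        )
        self.conn.commit()

    # -- objects ----------------------------------------------------------

    def _ensure_structure_table(self, structure: str) -> str:
        table = _table_name(structure)
        self.conn.execute(
            f"""CREATE TABLE IF NOT EXISTS {table} (
                image_id TEXT NOT NULL,
                object_id INTEGER NOT NULL,
                total_intensity REAL NOT NULL,
                volume_voxels INTEGER NOT NULL,
                centroid_x REAL NOT NULL,
                centroid_y REAL NOT NULL,
                centroid_z REAL NOT NULL,
                surface_coords BLOB,
                voxel_coords BLOB,
                PRIMARY KEY (image_id, object_id)
            )"""
        )
        return table

    def upsert_objects(self, objects: list[SubcellularObject]) -> int:
        """Insert objects idempotently.

        Re-inserting identical objects changes nothing; a duplicate key
        with *different* features raises.  Returns the number of rows now
        present for the affected (image, structure) pairs.
        """
        pairs = set()
        cur = self.conn.cursor()
        for o in objects:
            table = self._ensure_structure_table(o.structure_name)
            pairs.add((o.image_id, table))
            row = cur.execute(
                f"SELECT total_intensity, volume_voxels, centroid_x, centroid_y, centroid_z "
                f"FROM {table} WHERE image_id=? AND object_id=?",
                (o.image_id, o.object_id),
            ).fetchone()
            new = (
                float(o.total_intensity),
                int(o.volume_voxels),
                float(o.centroid[2]),
                float(o.centroid[1]),
                float(o.centroid[0]),
            )
            if row is not None:
                if tuple(row) != new:
                    raise ValueError(
                        f"object (image={o.image_id!r}, structure={o.structure_name!r}, "
                        f"id={o.object_id}) already stored with different features"
                    )
                continue
            cur.execute(
                f"INSERT INTO {table} ({_OBJECT_COLUMNS}) VALUES (?,?,?,?,?,?,?,?,?)",
                (o.image_id, o.object_id, *new, _pack(o.surface_coords), _pack(o.voxel_coords)),
            )
        self.conn.commit()
        total = 0
        for image_id, table in pairs or set():
            (n,) = cur.execute(
                f"SELECT COUNT(*) FROM {table} WHERE image_id=?", (image_id,)
            ).fetchone()
            total += n
        return total

    def get_objects(self, image_id: str, structure: str) -> list[SubcellularObject]:
        table = _table_name(structure)
        if not self._table_exists(table):
            return []
        rows = self.conn.execute(
            f"SELECT {_OBJECT_COLUMNS} FROM {table} WHERE image_id=? ORDER BY object_id",
            (image_id,),
        ).fetchall()
        objects = []
        for img, oid, total, vol, cx, cy, cz, surf, vox in rows:
            objects.append(
                SubcellularObject(
                    object_id=oid,
                    image_id=img,
                    structure_name=structure,
                    total_intensity=total,
                    volume_voxels=vol,
                    centroid=(cz, cy, cx),
                    surface_coords=_unpack(surf),
                    voxel_coords=_unpack(vox),
                    bounding_box=None,
                )
            )
        return objects

    def delete_image_objects(self, image_id: str, structure: str) -> None:
        table = _table_name(structure)
        if self._table_exists(table):
            self.conn.execute(f"DELETE FROM {table} WHERE image_id=?", (image_id,))
            self.conn.commit()

    # -- distances --------------------------------------------------------

    def replace_distances(
        self, image_id: str, structure_pair: str, records: list[DistanceRecord]
    ) -> int:
        """Replace all distance records for (image, pair); returns row count."""
        cur = self.conn.cursor()
        cur.execute(
            "DELETE FROM distances WHERE image_id=? AND structure_pair=?",
            (image_id, structure_pair),
        )
        cur.executemany(
            "INSERT INTO distances VALUES (?,?,?,?,?,?)",
            [
                (image_id, structure_pair, r.object_id, r.target_object_id, r.distance_um, r.method)
                for r in records
            ],
        )
        self.conn.commit()
        return len(records)

    def get_distances(self, image_id: str, structure_pair: str) -> list[DistanceRecord]:
        rows = self.conn.execute(
            "SELECT object_id, target_object_id, distance_um, method FROM distances "
            "WHERE image_id=? AND structure_pair=? ORDER BY object_id",
            (image_id, structure_pair),
        ).fetchall()
        return [
            DistanceRecord(image_id=image_id, object_id=o, target_object_id=t,
                           distance_um=d, method=m)
            for o, t, d, m in rows
        ]

    # -- measurements and profiles ---------------------------------------

    def replace_measurements(
        self, image_id: str, structure: str, estimates: list[MoleculeEstimate]
    ) -> int:
        cur = self.conn.cursor()
        cur.execute(
            "DELETE FROM measurements WHERE image_id=? AND structure=?", (image_id, structure)
        )
        cur.executemany(
            "INSERT INTO measurements VALUES (?,?,?,?,?)",
            [(image_id, structure, e.object_id, e.molecules, int(e.is_granule)) for e in estimates],
        )
        self.conn.commit()
        return len(estimates)

    def get_measurements(self, image_id: str, structure: str) -> list[MoleculeEstimate]:
        rows = self.conn.execute(
            "SELECT object_id, molecules, is_granule FROM measurements "
            "WHERE image_id=? AND structure=? ORDER BY object_id",
            (image_id, structure),
        ).fetchall()
        return [MoleculeEstimate(object_id=o, molecules=m, is_granule=bool(g)) for o, m, g in rows]

    def replace_profile(self, structure_pair: str, profile: DistributionProfile) -> int:
        cur = self.conn.cursor()
        cur.execute(
            "DELETE FROM profiles WHERE image_id=? AND structure_pair=? AND weight_mode=?",
            (profile.image_id, structure_pair, profile.weight_mode),
        )
        cur.executemany(
            "INSERT INTO profiles VALUES (?,?,?,?,?)",
            [
                (profile.image_id, structure_pair, float(d), float(p), profile.weight_mode)
                for d, p in zip(profile.grid, profile.cumulative_percent)
            ],
        )
        self.conn.commit()
        return len(profile.grid)

    def log_run(self, stage: str, image_id: str, params_json: str) -> None:
        self.conn.execute(
            "INSERT INTO runs (stage, image_id, params_json) VALUES (?,?,?)",
            (stage, image_id, params_json),
        )
        self.conn.commit()

    # -- export / backup --------------------------------------------------

    def _table_exists(self, table: str) -> bool:
        return (
            self.conn.execute(
                "SELECT COUNT(*) FROM sqlite_master WHERE type='table' AND name=?", (table,)
            ).fetchone()[0]
            > 0
        )

    def tables(self) -> list[str]:
        rows = self.conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table' AND name NOT LIKE 'sqlite_%' "
            "ORDER BY name"
        ).fetchall()
        return [r[0] for r in rows]

    def table_frame(self, table: str) -> pd.DataFrame:
        if not self._table_exists(table):
            raise ValueError(f"unknown table {table!r}; available: {', '.join(self.tables())}")
        df = pd.read_sql_query(f"SELECT * FROM {table}", self.conn)
        for col in df.columns:
            if df[col].dtype == object and df[col].map(lambda v: isinstance(v, bytes)).any():
                df[col] = df[col].map(
                    lambda v: base64.b64encode(v).decode("ascii") if isinstance(v, bytes) else v
                )
        return df

    def export_csv(self, table: str, path: str | Path) -> Path:
        """Export a table as CSV (header row; blobs base64-encoded).

        Numeric values are written with full ``repr`` precision and
        round-trip exactly through :meth:`import_csv`.
        """
        path = Path(path)
        self.table_frame(table).to_csv(path, index=False)
        return path

    def import_csv(self, table: str, path: str | Path) -> int:
        """Load rows exported by :meth:`export_csv` back into ``table``."""
        if not self._table_exists(table):
            raise ValueError(f"unknown table {table!r}; available: {', '.join(self.tables())}")
        df = pd.read_csv(path)
        info = self.conn.execute(f"PRAGMA table_info({table})").fetchall()
        blob_cols = {name for _, name, ctype, *_ in info if ctype.upper() == "BLOB"}
        records = []
        for _, row in df.iterrows():
            rec = []
            for col in df.columns:
                v = row[col]
                if col in blob_cols and isinstance(v, str):
                    v = base64.b64decode(v)
                elif pd.isna(v):
                    v = None
                rec.append(v)
            records.append(tuple(rec))
        placeholders = ",".join("?" * len(df.columns))
        self.conn.executemany(f"INSERT INTO {table} VALUES ({placeholders})", records)
        self.conn.commit()
        return len(records)

    def backup(self, path: str | Path) -> Path:
        """Write the backend's native SQL dump of every table."""
        path = Path(path)
        with open(path, "w") as fh:
            for line in self.conn.iterdump():
                fh.write(line + "\n")
        return path

    @classmethod
    def restore(cls, dump_path: str | Path, store_path: str | Path = ":memory:") -> "ObjectStore":
        """Recreate a store from a :meth:`backup` dump."""
        store = cls.__new__(cls)
        store.path = str(store_path)
        store.conn = sqlite3.connect(store.path)
        with open(dump_path) as fh:
            store.conn.executescript(fh.read())
        store.conn.commit()
        return store
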