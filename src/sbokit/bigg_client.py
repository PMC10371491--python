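"""Optional EC back-fill from the BiGG Models web API.

Many published genome-scale models omit EC annotations.  For such models the
annotator can query BiGG's reaction resources and read EC numbers out of
their database-link sections.  The network gateway is injectable so the rest
of the tool — and its entire test suite — stays hermetic; a strict offline
mode guarantees zero network calls and degrades gracefully to the generic
biochemical term.  Results are cached in a small on-disk SQLite table keyed
by reaction id.
"""

from __future__ import annotations

import json
import logging
import sqlite3
import time
import urllib.error
import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Protocol, Tuple, Union

from .sbo_knowledge import ECNumber

log = logging.getLogger(__name__)

__all__ = ["ECFetchResult", "Gateway", "UrllibGateway", "ECCache",
           "fetch_reaction_ec", "BIGG_UNIVERSAL_URL"]

BIGG_UNIVERSAL_URL = "http://bigg.ucsd.edu/api/v2/universal/reactions/{rid}"


@dataclass(frozen=True)
class ECFetchResult:
    reaction_id: str
    ec_numbers: Tuple[ECNumber, ...]
    source: str  # cache | remote | absent

    def __post_init__(self):
        if self.source not in ("cache", "remote", "absent"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "absent" and self.ec_numbers:
            raise ValueError("absent result must carry no EC numbers")


class Gateway(Protocol):
    """Minimal network gateway: fetch a URL, return bytes or None for 404."""

    def get(self, url: str) -> Optional[bytes]: ...


class UrllibGateway:
    """Live gateway with one retry; used only outside the hermetic tests."""

    def __init__(self, timeout: float = 10.0, retries: int = 1,
                 backoff: float = 1.0):
        self.timeout = timeout
        self.retries = retries
        self.backoff = backoff

    def get(self, url: str) -> Optional[bytes]:
        last_error = None
        for attempt in range(self.retries + 1):
            try:
                with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                    return resp.read()
            except urllib.error.HTTPError as exc:
                if exc.code == 404:
                    return None
                last_error = exc
            except (urllib.error.URLError, OSError) as exc:
                last_error = exc
            if attempt < self.retries:
                time.sleep(self.backoff)
        raise ConnectionError(f"could not reach {url}: {last_error}")


class ECCache:
    """On-disk cache table (reaction_id, ec JSON list, fetched_at)."""

    def __init__(self, path: Union[str, Path] = ":memory:"):
        self._conn = sqlite3.connect(str(path))
        self._conn.execute(
            "CREATE TABLE IF NOT EXISTS ec_cache ("
            " reaction_id TEXT PRIMARY KEY,"
            " ecs TEXT NOT NULL,"
            " fetched_at REAL NOT NULL)"
        )

    def get(self, reaction_id: str) -> Optional[List[ECNumber]]:
        row = self._conn.execute(
            "SELECT ecs FROM ec_cache WHERE reaction_id = ?", (reaction_id,)
        ).fetchone()
        if row is None:
            return None
        return [ECNumber.parse(s) for s in json.loads(row[0])]

    def put(self, reaction_id: str, ecs: List[ECNumber]) -> None:
        self._conn.execute(
            "INSERT OR REPLACE INTO ec_cache VALUES (?, ?, ?)",
            (reaction_id, json.dumps([str(e) for e in ecs]), time.time()),
        )
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()


def _strip_model_prefix(reaction_id: str) -> str:
    return reaction_id[2:] if reaction_id.startswith("R_") else reaction_id


def _parse_bigg_ecs(payload: bytes) -> List[ECNumber]:
    data = json.loads(payload.decode("utf-8"))
    links = data.get("database_links", {})
    entries = links.get("EC Number", []) or links.get("ec-code", [])
    ecs: List[ECNumber] = []
    for entry in entries:
        raw = entry.get("id") if isinstance(entry, dict) else entry
        if not raw:
            continue
        try:
            ec = ECNumber.parse(str(raw))
        except ValueError:
            log.warning("skipping malformed EC from BiGG: %r", raw)
            continue
        if ec not in ecs:
            ecs.append(ec)
    return ecs


def fetch_reaction_ec(bigg_reaction_id: str,
                      gateway: Optional[Gateway] = None,
                      cache: Optional[ECCache] = None,
                      offline: bool = False) -> ECFetchResult:
    """EC numbers for a BiGG reaction id, via cache, remote, or neither.

    Offline mode still consults the cache but guarantees no network call.
    Remote failures degrade to an absent result with a warning; annotation
    then falls back to the generic biochemical term rather than aborting.
    """
    rid = _strip_model_prefix(bigg_reaction_id)
    if cache is not None:
        hit = cache.get(rid)
        if hit is not None:
            return ECFetchResult(rid, tuple(hit), "cache")
    if offline or gateway is None:
        return ECFetchResult(rid, (), "absent")
    try:
        payload = gateway.get(BIGG_UNIVERSAL_URL.format(rid=rid))
    except ConnectionError as exc:
        log.warning("BiGG lookup failed for %s: %s", rid, exc)
        return ECFetchResult(rid, (), "absent")
    if payload is None:
        if cache is not None:
            cache.put(rid, [])
        return ECFetchResult(rid, (), "absent")
    ecs = _parse_bigg_ecs(payload)
    if cache is not None:
        cache.put(rid, ecs)
    return ECFetchResult(rid, tuple(ecs), "remote")
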