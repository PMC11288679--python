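"""Hour-binned queen-worker encounter kinetics.

Three statistics summarize how queens accumulate strength and entropy:
the mean proportion of the workforce contacted per hour, the mean number of
contacts per contacted worker per hour (zeros excluded), and the hour-to-hour
conservation of contacted-worker identity (the fraction of hour t-1 partners
contacted again in hour t).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

__all__ = [
    "HourlyContacts",
    "bin_queen_contacts",
    "workers_per_hour",
    "contacts_per_worker_per_hour",
    "identity_conservation",
]


@dataclass
class HourlyContacts:
    """Queen contact counts binned by hour.

    ``counts[t]`` maps worker id -> number of queen contacts in hour t, for
    contiguous hours t = 0 .. n_hours-1 (hours without contacts hold empty
    counters).
    """

    counts: list[Counter]
    flags: dict = field(default_factory=dict)

    @property
    def n_hours(self) -> int:
        return len(self.counts)

    def partners(self, t: int) -> set:
        return set(self.counts[t])

    def total_contacts(self) -> Counter:
        out: Counter = Counter()
        for c in self.counts:
            out.update(c)
        return out


def bin_queen_contacts(
    events,
    queen_id,
    hour_length_s: float = 3600.0,
    n_hours: int | None = None,
) -> HourlyContacts:
    """Bin queen interaction events into hours by event start time.

    ``events`` is an iterable of objects with ``ant_i``, ``ant_j`` and
    ``start_s`` attributes.  Events not involving the queen are ignored.
    """
    if hour_length_s <= 0:
        raise ConfigError("hour_length_s must be positive")
    binned: dict[int, Counter] = {}
    max_hour = -1
    n_queen_events = 0
    for e in events:
        if e.ant_i == queen_id:
            partner = e.ant_j
        elif e.ant_j == queen_id:
            partner = e.ant_i
        else:
            continue
        n_queen_events += 1
        t = int(e.start_s // hour_length_s)
        binned.setdefault(t, Counter())[partner] += 1
        max_hour = max(max_hour, t)
    H = n_hours if n_hours is not None else max_hour + 1
    hc = HourlyContacts(counts=[binned.get(t, Counter()) for t in range(H)])
    if n_queen_events == 0:
        hc.flags["no_queen_events"] = True
        warnings.warn("no queen interaction events; empty hourly contacts")
    return hc


def workers_per_hour(hc: HourlyContacts, n_workers: int) -> float:
    """Mean proportion of the workforce contacted per hour.

    Hours without contacts contribute 0 to the mean.
    """
    if hc.n_hours < 1:
        raise ConfigError("need at least one hour")
    if n_workers < 1:
        raise ConfigError("n_workers must be positive")
    return float(np.mean([len(c) / n_workers for c in hc.counts]))


def contacts_per_worker_per_hour(hc: HourlyContacts) -> float:
    """Mean contact count over (hour, worker) pairs with >= 1 contact.

    Returns NaN (with a warning) when the queen contacted no one at all:
    zeros never enter the mean.
    """
    vals = [v for c in hc.counts for v in c.values()]
    if not vals:
        warnings.warn("no queen contacts; contacts per worker per hour undefined")
        return float("nan")
    return float(np.mean(vals))


def identity_conservation(hc: HourlyContacts) -> float:
    """Mean over hours t >= 1 of |A_t intersect A_{t-1}| / |A_{t-1}|.

    A_t is the set of workers the queen contacted in hour t.  Hours whose
    predecessor set is empty are skipped; if every predecessor is empty the
    statistic is undefined (NaN with a warning).
    """
    if hc.n_hours < 2:
        raise ConfigError("identity conservation needs >= 2 hours")
    ratios = []
    for t in range(1, hc.n_hours):
        prev = hc.partners(t - 1)
        if not prev:
            continue
        ratios.append(len(hc.partners(t) & prev) / len(prev))
    if not ratios:
        warnings.warn("all predecessor hours empty; identity conservation undefined")
        return float("nan")
    return float(np.mean(ratios))
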