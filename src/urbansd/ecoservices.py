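"""Ecosystem-service valuation: availability matrix x unit values x areas.

Each of the nine land classes (five ecosystem subtypes, four green-
infrastructure subtypes) provides a subset of ten ecosystem services; a
service provided by a class is valued at a per-hectare-per-month unit value
in the shape of the TEEB benefit-transfer database. The shipped unit values
are SYNTHETIC order-of-magnitude placeholders (the source database's local
values are not public data of this package); the availability matrix is the
study's. Every downstream result that matters is a ratio or ordering, and
is invariant to the placeholder magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SERVICES = (
    "Food",
    "Materials",
    "Extreme events",
    "Air quality",
    "Water purification",
    "Climate regulation",
    "Hydrological cycle management",
    "BioControl",
    "Pollination",
    "Recreational use",
)

ECO_CLASSES = (
    "Forests and Heathland",
    "Croplands",
    "Coastal ecosystems",
    "Inland waters, wetlands and estuaries",
    "Grasslands and Pastures",
)

GI_CLASSES = (
    "Green Urban Areas",
    "SUDS",
    "Urban Gardens",
    "Green Corridors",
)

LAND_CLASSES = ECO_CLASSES + GI_CLASSES

# Availability matrix: service -> classes providing it.
_AVAILABILITY: dict[str, tuple[str, ...]] = {
    "Food": ECO_CLASSES + ("Urban Gardens",),
    "Materials": (
        "Forests and Heathland",
        "Croplands",
        "Grasslands and Pastures",
        "Urban Gardens",
    ),
    "Extreme events": (
        "Forests and Heathland",
        "Coastal ecosystems",
        "Inland waters, wetlands and estuaries",
        "Green Urban Areas",
        "SUDS",
        "Green Corridors",
    ),
    "Air quality": ECO_CLASSES
    + ("Green Urban Areas", "Urban Gardens", "Green Corridors"),
    "Water purification": (
        "Forests and Heathland",
        "Croplands",
        "Inland waters, wetlands and estuaries",
        "Grasslands and Pastures",
    )
    + GI_CLASSES,
    "Climate regulation": (
        "Forests and Heathland",
        "Croplands",
        "Inland waters, wetlands and estuaries",
        "Grasslands and Pastures",
    )
    + GI_CLASSES,
    "Hydrological cycle management": ECO_CLASSES + GI_CLASSES,
    "BioControl": ECO_CLASSES + GI_CLASSES,
    "Pollination": (
        "Forests and Heathland",
        "Croplands",
        "Grasslands and Pastures",
    )
    + GI_CLASSES,
    "Recreational use": ECO_CLASSES
    + ("Green Urban Areas", "Urban Gardens", "Green Corridors"),
}

# Synthetic placeholder unit values, EUR/ha/month, applied uniformly to every
# class providing the service. NOT source-database data; editable via the CSV.
_PLACEHOLDER_UNIT_VALUES: dict[str, float] = {
    "Food": 40.0,
    "Materials": 10.0,
    "Extreme events": 25.0,
    "Air quality": 30.0,
    "Water purification": 35.0,
    "Climate regulation": 45.0,
    "Hydrological cycle management": 30.0,
    "BioControl": 15.0,
    "Pollination": 20.0,
    "Recreational use": 50.0,
}


@dataclass
class ValuationTable:
    """(land class x service) availability flags and EUR/ha/month unit values."""

    frame: pd.DataFrame  # columns: land_class, service, available, unit_value

    def __post_init__(self) -> None:
        f = self.frame
        bad_class = set(f["land_class"]) - set(LAND_CLASSES)
        bad_service = set(f["service"]) - set(SERVICES)
        if bad_class or bad_service:
            raise ValueError(
                f"unknown names {sorted(bad_class | bad_service)}; land classes "
                f"are {list(LAND_CLASSES)} and services {list(SERVICES)}"
            )
        if (f["unit_value_eur_per_ha_month"] < 0).any():
            raise ValueError("unit values must be non-negative")
        masked = f.loc[f["available"] == 0, "unit_value_eur_per_ha_month"]
        if (masked != 0).any():
            raise ValueError("unit value must be 0 where the service is unavailable")
        self._matrix = (
            f.assign(
                value=f["available"] * f["unit_value_eur_per_ha_month"]
            )
            .pivot(index="service", columns="land_class", values="value")
            .reindex(index=list(SERVICES), columns=list(LAND_CLASSES))
            .fillna(0.0)
            .to_numpy()
        )

    def service_available(self, land_class: str, service: str) -> bool:
        """Availability flag of one (class, service) cell."""
        if land_class not in LAND_CLASSES:
            raise ValueError(
                f"unknown land class {land_class!r}; choose from {list(LAND_CLASSES)}"
            )
        if service not in SERVICES:
            raise ValueError(
                f"unknown service {service!r}; choose from {list(SERVICES)}"
            )
        row = self.frame[
            (self.frame["land_class"] == land_class)
            & (self.frame["service"] == service)
        ]
        return bool(row["available"].iloc[0]) if len(row) else False

    @property
    def matrix(self) -> np.ndarray:
        """(n_services, n_classes) array of availability-masked unit values."""
        return self._matrix

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ValuationTable":
        return cls(pd.read_csv(path))


def default_table() -> ValuationTable:
    """The shipped fixture: the study's availability matrix with synthetic
    placeholder unit values."""
    rows = []
    for land_class in LAND_CLASSES:
        for service in SERVICES:
            avail = int(land_class in _AVAILABILITY[service])
            rows.append(
                {
                    "land_class": land_class,
                    "service": service,
                    "available": avail,
                    "unit_value_eur_per_ha_month": (
                        _PLACEHOLDER_UNIT_VALUES[service] if avail else 0.0
                    ),
                }
            )
    return ValuationTable(pd.DataFrame(rows))


def load_table() -> ValuationTable:
    """Load the packaged valuation-table fixture (editable CSV)."""
    path = resources.files("urbansd.data").joinpath("valuation_table.csv")
    with resources.as_file(path) as p:
        return ValuationTable.from_csv(p)


def subtype_areas(
    area_eco: float,
    area_gi: float,
    eco_shares: Mapping[str, float],
    gi_shares: Mapping[str, float],
) -> np.ndarray:
    """Hectares per land class, applying the static subtype shares to the
    aggregate ecosystem and GI stocks (ordered as LAND_CLASSES)."""
    return np.array(
        [area_eco * eco_shares[c] for c in ECO_CLASSES]
        + [area_gi * gi_shares[c] for c in GI_CLASSES]
    )


def monthly_es_value(
    areas: Iterable[float] | np.ndarray, table: ValuationTable
) -> tuple[dict[str, float], float]:
    """Monthly EUR value per service and in total, linear in every area.

    value(s) = sum over classes of area x unit value x availability.
    """
    areas = np.asarray(list(areas), dtype=float)
    per_service_vec = table.matrix @ areas
    per_service = dict(zip(SERVICES, per_service_vec))
    return per_service, float(per_service_vec.sum())


def recreation_value(
    areas: Iterable[float] | np.ndarray, table: ValuationTable
) -> float:
    """The 'Recreational use' row of the valuation — the leisure/social
    quality-of-life indicator, EUR/month."""
    per_service, _ = monthly_es_value(areas, table)
    return per_service["Recreational use"]
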