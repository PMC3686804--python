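"""Region rule tables for grouping survey circles into analysis regions.

A rule table is an ordered list of dictionaries; each rule may constrain
the coastal/interior status of a circle (``coastal``: True, False or None
for "either") and bound its latitude and longitude.  The first matching
rule wins.  Circles whose centre lies less than ``COASTAL_THRESHOLD_KM``
from the coast are coastal; at or beyond the threshold (or with no coast
distance at all, e.g. landlocked states) they are interior.

The shipped default groups Pacific-flyway winter circles into the eight
regions used for *Aechmophorus* grebe trend analysis: it keys on the 51°
split between Alaska/northern BC and the Salish Sea, the 42° southern
limit of the northern coastal ranges, and the 36° split between northern
and southern coastal California.  The Salish Sea (inland waterways east
of the outer Washington coast) is separated from the outer coast by
longitude.  The table is configuration, not code: pass your own list, or
load one from YAML with :func:`load_region_rules`.
"""

from __future__ import annotations

import math

import yaml

from .errors import RegionAssignmentError

#: Circles closer than this to the coast count as coastal; >= is interior.
COASTAL_THRESHOLD_KM = 50.0

DEFAULT_REGION_RULES = [
    {"region": "Alaska/North BC", "coastal": True, "lat_min": 51.0},
    # Inland waterways: Georgia Strait / Puget Sound box, then the
    # Strait of Juan de Fuca margin further west.
    {"region": "Salish Sea", "coastal": True, "lat_min": 46.5, "lat_max": 51.0,
     "lon_min": -123.5},
    {"region": "Salish Sea", "coastal": True, "lat_min": 47.8, "lat_max": 51.0,
     "lon_min": -124.8},
    {"region": "Outer Washington/Oregon Coast", "coastal": True,
     "lat_min": 42.0, "lat_max": 51.0},
    {"region": "Northern California Coast", "coastal": True,
     "lat_min": 36.0, "lat_max": 42.0},
    {"region": "Southern California Coast", "coastal": True, "lat_max": 36.0},
    {"region": "Northern Interior", "coastal": False, "lat_min": 42.0},
    {"region": "Interior California/Nevada", "coastal": False,
     "lat_min": 35.0, "lat_max": 42.0, "lon_max": -114.0},
    {"region": "Southwestern Interior", "coastal": False},
]

REGION_NAMES = [rule["region"] for rule in DEFAULT_REGION_RULES]


def is_coastal(coast_distance_km) -> bool:
    """Apply the 50-km rule; a missing distance means interior (landlocked)."""
    if coast_distance_km is None:
        return False
    if isinstance(coast_distance_km, float) and math.isnan(coast_distance_km):
        return False
    return float(coast_distance_km) < COASTAL_THRESHOLD_KM


def _matches(rule: dict, latitude: float, longitude: float, coastal: bool) -> bool:
    if rule.get("coastal") is not None and rule["coastal"] != coastal:
        return False
    if "lat_min" in rule and latitude < rule["lat_min"]:
        return False
    if "lat_max" in rule and latitude >= rule["lat_max"]:
        return False
    if "lon_min" in rule and longitude < rule["lon_min"]:
        return False
    if "lon_max" in rule and longitude >= rule["lon_max"]:
        return False
    return True


def assign_region(latitude: float, longitude: float, coast_distance_km=None,
                  rules=None, circle_id=None) -> str:
    """Return the region label of the first matching rule.

    Raises
    ------
    RegionAssignmentError
        If no rule matches the circle.
    """
    if rules is None:
        rules = DEFAULT_REGION_RULES
    coastal = is_coastal(coast_distance_km)
    for rule in rules:
        if _matches(rule, latitude, longitude, coastal):
            return rule["region"]
    label = f"circle {circle_id!r} " if circle_id is not None else ""
    raise RegionAssignmentError(
        f"{label}(lat={latitude}, lon={longitude}, coastal={coastal}) "
        "matched no rule in the region table"
    )


def load_region_rules(path) -> list[dict]:
    """Load a rule table from a YAML file (a list of rule mappings)."""
    with open(path) as fh:
        rules = yaml.safe_load(fh)
    if not isinstance(rules, list) or not all("region" in r for r in rules):
        raise ValueError(f"{path}: expected a YAML list of rules with 'region' keys")
    return rules


def save_region_rules(rules, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(list(rules), fh, sort_keys=False)
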