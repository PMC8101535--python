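"""Exception types shared across the pipeline stages."""


class SmokeHIAError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SmokeHIAError):
    """A synthetic-data or run configuration is internally inconsistent."""


class ImputationError(SmokeHIAError):
    """An unmonitored county-day has no monitored neighbor to borrow from."""

    def __init__(self, county_id, date):
        self.county_id = county_id
        self.date = date
        super().__init__(
            f"cannot impute PM2.5 for county {county_id!r} on {date}: "
            "no monitored neighboring county reported that day"
        )


class MissingDemographicsError(SmokeHIAError):
    """A county present in the exposure table has no demographics row."""

    def __init__(self, county_ids):
        self.county_ids = list(county_ids)
        super().__init__(
            "no demographics for county/counties: " + ", ".join(map(str, self.county_ids))
        )


class RSDEstimationError(SmokeHIAError):
    """Spatial-variation estimation is impossible from the given monitor network."""
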