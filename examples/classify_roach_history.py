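"""Classify two lakes from their historical roach survey records.

One lake shows the classic extirpation signal (present before 1960,
absent through the heavy-acidification decades, reappearing after
restocking); the other has a persistent population.
"""

from borealacid import LakeSurveyHistory, SurveyRecord, classify_biological


def history(lake_id, records):
    return LakeSurveyHistory(
        lake_id=lake_id,
        records=[SurveyRecord(lake_id, y, p) for y, p in records],
    )


extirpated = history(
    "Agntjärnen",
    [(1935, True), (1948, True), (1955, True),
     (1972, False), (1979, False), (1986, False),
     (1995, False), (2006, True)],
)
persistent = history(
    "Abbortjärnen",
    [(1940, True), (1952, True),
     (1970, True), (1984, True),
     (1998, True)],
)

for lake in (extirpated, persistent):
    res = classify_biological(lake)
    print(f"{lake.lake_id}: {res.status.value}")
    print(f"  presence fraction before 1960:   {res.p1_fraction:.2f}")
    print(f"  presence fraction 1960-1990:     {res.p2_fraction:.2f}")
    print(f"  recolonized after 1990:          {res.recolonized}")

print()
print("A lake is called acidified when >=75% of pre-1960 surveys found roach")
print("but <=25% of heavy-period surveys did; persistent presence above 90%")
print("in both periods is nonacidified. The restocked lake keeps its")
print("acidified status but carries the recolonization flag.")
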