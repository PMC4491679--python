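"""Out-of-pocket savings from hypofractionating a proton course.

Compare the 44-fraction standard course against a 25-fraction
hypofractionated one under a Monday-start weekday calendar, pricing the
saved days at per-diem meal/lodging rates and lost wages.
"""

from protonplan.costs import annual_wage_to_daily, savings, treatment_calendar_days

print(f"44-fraction course: {treatment_calendar_days(44)} calendar days (incl. 5 planning days)")
print(f"25-fraction course: {treatment_calendar_days(25)} calendar days")

report = savings(n_standard=44, n_hypo=25)
print(f"\n{report.describe()}")
print(f"Daily wage behind the estimate: "
      f"${annual_wage_to_daily(52100, 'workday'):.0f}/workday from a $52,100 annual income")

print(
    "\nDropping 19 fractions shortens the stay by 27 calendar days (weekends\n"
    "inside the delivery span count); at $200/day in lost wages that is\n"
    "$5400, plus up to ~$1900 in meals and ~$5000 in lodging for a patient\n"
    "staying near the treatment centre."
)
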