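# Accepted time-unit tokens for free number+unit answers, mapped to the
# canonical unit enum. Unknown units are rejected, never guessed.
minute: [minute, minutes, min, mins, m]
hour: [hour, hours, hr, hrs, h]
day: [day, days, d]
week: [week, weeks, wk, wks, w]
month: [month, months, mo, mos]
year: [year, years, yr, yrs, y]
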