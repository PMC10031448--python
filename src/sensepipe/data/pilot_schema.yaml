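# Pilot-study sampling schema (default registry profile).
#
# Canonical keys per sensor:
#   mode     : interval | interval_burst | event | daily
#   period_s : seconds between acquisitions (interval, interval_burst)
#   burst_s  : seconds of continuous sampling per acquisition (interval_burst)
#   os       : list drawn from [android, ios]; sensors absent on an OS never
#              contribute to that OS's expected counts
#
# Light is exposed to iOS in some framework builds but the underlying API is
# not available there; it defaults to android-only and is a config edit away.
sensors:
  accelerometer: {mode: interval_burst, period_s: 5, burst_s: 1, os: [android, ios]}
  activity: {mode: event, os: [android, ios]}
  air_quality: {mode: interval, period_s: 3600, os: [android, ios]}
  app_use: {mode: interval, period_s: 1800, os: [android]}
  battery: {mode: event, os: [android, ios]}
  bluetooth: {mode: interval, period_s: 300, os: [android, ios]}
  calendar: {mode: daily, os: [android, ios]}
  connectivity: {mode: event, os: [android, ios]}
  device: {mode: daily, os: [android, ios]}
  gyroscope: {mode: interval_burst, period_s: 5, burst_s: 1, os: [android, ios]}
  installed_apps: {mode: daily, os: [android]}
  light: {mode: interval_burst, period_s: 60, burst_s: 10, os: [android]}
  location: {mode: interval, period_s: 60, os: [android, ios]}
  memory: {mode: interval, period_s: 60, os: [android]}
  mobility: {mode: event, os: [android, ios]}
  noise: {mode: interval, period_s: 60, os: [android]}
  pedometer: {mode: event, os: [android, ios]}
  screen: {mode: event, os: [android]}
  weather: {mode: interval, period_s: 3600, os: [android, ios]}
  wifi: {mode: interval, period_s: 600, os: [android, ios]}
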