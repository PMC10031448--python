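# Framework default sampling frequencies (alternate profile, never merged
# with the pilot profile).  Notable difference: wifi every 10 seconds here
# versus every 10 minutes in the pilot profile.  Continuous inertial
# streams are modelled as back-to-back 1-second bursts.
sensors:
  accelerometer: {mode: interval_burst, period_s: 1, burst_s: 1, os: [android, ios]}
  activity: {mode: event, os: [android, ios]}
  air_quality: {mode: interval, period_s: 3600, os: [android, ios]}
  app_use: {mode: interval, period_s: 1800, os: [android]}
  battery: {mode: event, os: [android, ios]}
  bluetooth: {mode: interval, period_s: 300, os: [android, ios]}
  calendar: {mode: daily, os: [android, ios]}
  connectivity: {mode: event, os: [android, ios]}
  device: {mode: event, os: [android, ios]}
  gyroscope: {mode: interval_burst, period_s: 1, burst_s: 1, os: [android, ios]}
  installed_apps: {mode: daily, os: [android]}
  light: {mode: interval, period_s: 60, os: [android]}
  location: {mode: interval, period_s: 60, os: [android, ios]}
  memory: {mode: interval, period_s: 60, os: [android]}
  mobility: {mode: event, os: [android, ios]}
  noise: {mode: interval, period_s: 300, os: [android]}
  pedometer: {mode: event, os: [android, ios]}
  screen: {mode: event, os: [android]}
  weather: {mode: interval, period_s: 3600, os: [android, ios]}
  wifi: {mode: interval, period_s: 10, os: [android, ios]}
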