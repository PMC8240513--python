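event,time,date,t_air,t_dew,rh,radiation,dew_flag
1,12:00,01-Aug-2017,15.1,5.1,51.4,2.0,0
1,13:00,01-Aug-2017,16.2,4.5,46.2,2.1,0
1,14:00,01-Aug-2017,16.5,2.7,39.7,2.0,0
1,15:00,01-Aug-2017,16.5,1.8,37.3,1.7,0
1,16:00,01-Aug-2017,16.2,2.8,40.6,1.2,0
1,17:00,01-Aug-2017,13.4,3.0,49.7,0.6,0
1,18:00,01-Aug-2017,11.7,2.9,55.2,0.1,0
1,07:00,02-Aug-2017,3.6,3.4,99.0,0.0,1
1,08:00,02-Aug-2017,5.7,5.2,96.7,0.2,1
1,09:00,02-Aug-2017,8.8,4.8,76.5,0.7,0
1,10:00,02-Aug-2017,11.0,3.8,61.3,1.3,0
1,11:00,02-Aug-2017,13.1,4.1,54.7,1.8,0
1,12:00,02-Aug-2017,14.9,4.0,48.2,2.0,0
2,12:00,17-Aug-2017,16.3,4.3,45.1,2.4,0
2,13:00,17-Aug-2017,16.7,4.6,44.9,2.5,0
2,14:00,17-Aug-2017,16.9,4.3,43.3,2.3,0
2,15:00,17-Aug-2017,16.8,4.1,43.0,2.0,0
2,16:00,17-Aug-2017,16.4,3.9,43.4,1.4,0
2,17:00,17-Aug-2017,15.1,4.2,48.4,0.3,0
2,18:00,17-Aug-2017,14.0,4.1,51.1,0.1,0
2,07:00,18-Aug-2017,7.2,4.3,82.3,0.0,0
2,08:00,18-Aug-2017,8.2,4.5,77.5,0.2,0
2,09:00,18-Aug-2017,9.4,5.0,74.1,0.8,0
2,10:00,18-Aug-2017,10.6,5.1,68.9,1.5,0
2,11:00,18-Aug-2017,11.3,4.4,63.0,1.7,0
2,12:00,18-Aug-2017,12.1,3.7,56.7,1.6,0
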