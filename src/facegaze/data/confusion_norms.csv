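stimulus,response,mean_pct,sd_pct
happiness,happiness,97.6,4.9
happiness,surprise,1.5,4.8
happiness,anger,0.1,0.4
happiness,sadness,0.0,0.3
happiness,disgust,0.8,1.0
happiness,fear,0.0,0.2
surprise,happiness,1.7,2.1
surprise,surprise,95.3,4.5
surprise,anger,0.2,0.6
surprise,sadness,0.1,0.5
surprise,disgust,0.4,0.8
surprise,fear,2.3,3.6
anger,happiness,0.0,0.3
anger,surprise,0.6,1.6
anger,anger,92.7,8.8
anger,sadness,1.2,2.1
anger,disgust,3.8,6.0
anger,fear,1.7,1.8
sadness,happiness,0.3,1.2
sadness,surprise,0.1,2.2
sadness,anger,1.4,2.6
sadness,sadness,75.2,20.5
sadness,disgust,7.7,10.9
sadness,fear,14.3,12.4
disgust,happiness,0.1,0.4
disgust,surprise,0.8,1.4
disgust,anger,10.8,15.9
disgust,sadness,4.9,10.1
disgust,disgust,80.4,18.4
disgust,fear,3.0,5.8
fear,happiness,0.5,0.8
fear,surprise,26.0,23.7
fear,anger,0.8,1.6
fear,sadness,2.4,3.5
fear,disgust,10.5,12.4
fear,fear,59.8,20.4
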